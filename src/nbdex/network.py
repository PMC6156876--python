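"""Partial-correlation gene networks from model-adjusted expression.

Expression is first adjusted to retain only the effect of interest (diet)
plus the residual: on the working (linearised) scale of the NB fit, the
adjusted value per sample is the fitted diet component plus the working
residual (y - mu)/mu.  All other fitted components (sex/time, batch, pen,
sire, covariates) are removed.  "Counts pre-adjusted" cannot be literal
counts once multiplicative effects are removed, so the linear-predictor
scale is used.

Partial correlations come from the (pseudo)inverse P of the gene-gene
correlation matrix: pcor_ij = -P_ij / sqrt(P_ii * P_jj).  With more genes
than samples the correlation matrix is singular and the Moore-Penrose
pseudoinverse is used (matching the behaviour of the standard
partial-correlation packages); an optional Ledoit-Wolf-style shrinkage
toward the identity is available but off by default.  Edges require a
partial correlation strictly greater than |0.8|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .glm import NBFit
from .models import DesignInfo

__all__ = [
    "adjust_expression",
    "partial_correlations",
    "build_network",
    "edge_table",
    "write_graphml",
]


def adjust_expression(
    fits: dict[str, NBFit], keep_effect: str = "diet"
) -> pd.DataFrame:
    """Per-gene adjusted values: kept-effect component + working residual.

    ``fits`` maps gene_id -> fitted model on a common sample set.  Genes
    whose fit is missing or not converged are dropped.  Returns a genes x
    samples DataFrame on the working scale.
    """
    rows, ids = [], []
    n_ref = None
    for gene_id, fit in fits.items():
        if fit is None or not fit.converged:
            continue
        info: DesignInfo = fit.design_info
        cols = info.term_columns(keep_effect)
        # interaction terms containing the kept effect stay removed: the
        # retained component is the marginal kept-effect column block only
        names = [info.colnames[i] for i in cols]
        pos = [fit.colnames.index(nm) for nm in names if nm in fit.colnames]
        kept = fit.X[:, pos] @ fit.beta[pos] if pos else np.zeros(len(fit.y))
        value = kept + fit.working_residuals()
        if n_ref is None:
            n_ref = len(value)
        elif len(value) != n_ref:
            raise ValueError("fits do not share a common sample set")
        rows.append(value)
        ids.append(gene_id)
    if not rows:
        raise ValueError("no converged fits to adjust")
    return pd.DataFrame(np.vstack(rows), index=ids)


def partial_correlations(X: pd.DataFrame, shrinkage: float = 0.0) -> pd.DataFrame:
    """Gene x gene partial correlations given all remaining genes.

    ``X`` is genes x samples.  Requires >=3 genes and >=4 samples and no
    constant gene.  ``shrinkage`` in [0, 1) blends the correlation matrix
    with the identity before inversion (0 = plain pseudoinverse).
    """
    vals = X.to_numpy(dtype=float)
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    if vals.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = list(X.index[sd == 0])
        raise ValueError(f"constant gene(s): {bad}")
    corr = np.corrcoef(vals)
    if shrinkage:
        corr = (1.0 - shrinkage) * corr + shrinkage * np.eye(len(corr))
    P = np.linalg.pinv(corr, hermitian=True)
    d = np.sqrt(np.abs(np.diag(P)))
    pcor = -P / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = 0.5 * (pcor + pcor.T)
    return pd.DataFrame(pcor, index=X.index, columns=X.index)


def build_network(
    pcor: pd.DataFrame,
    threshold: float = 0.8,
    node_attrs: pd.DataFrame | None = None,
    steers_only_samples: bool = True,
) -> nx.Graph:
    """Undirected network with edges where |pcor| > threshold (strict).

    ``node_attrs`` (indexed by gene id) may carry tissue and regulation
    labels copied onto the nodes.  The caller is responsible for having
    restricted cross-tissue inputs to the common (steer) samples before
    computing partial correlations; the flag is recorded on the graph.
    """
    if not np.allclose(pcor.to_numpy(), pcor.to_numpy().T, atol=1e-8):
        raise ValueError("partial-correlation matrix must be symmetric")
    g = nx.Graph(steers_only=steers_only_samples, threshold=threshold)
    for gene in pcor.index:
        attrs = {}
        if node_attrs is not None and gene in node_attrs.index:
            attrs = node_attrs.loc[gene].to_dict()
        g.add_node(gene, **attrs)
    genes = list(pcor.index)
    vals = pcor.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = vals[i, j]
            if abs(r) > threshold:
                g.add_edge(genes[i], genes[j], pcor=float(r), sign="+" if r > 0 else "-")
    return g


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export with tissue/regulation node attributes preserved."""
    clean = g.copy()
    for _, attrs in clean.nodes(data=True):
        for k, v in list(attrs.items()):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                attrs[k] = ""
    nx.write_graphml(clean, path)


def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"gene_a": u, "gene_b": v, "pcor": d["pcor"], "sign": d["sign"]}
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcor", "sign"])
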