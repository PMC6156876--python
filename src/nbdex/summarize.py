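"""FDR adjustment, DEG calling, the two-stage contrast rule, and summary
tables (Venn region counts, volcano tables).

q-values are Benjamini-Hochberg step-up values, applied per model term
across genes (not jointly across terms).  DEG are called at q <= 0.05.
Contrast-based DEG use a two-stage rule: the gating term (interaction or
time main effect) must pass q <= alpha_q, and the contrast itself must pass
an unadjusted p < alpha_p.  Volcano tables drop extreme rows (FC outside
[1/5, 5] or q below 1e-6), matching the published display convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "call_deg",
    "contrast_within_interaction",
    "venn_counts",
    "volcano_table",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN p-values (non-converged genes) are excluded from the number of
    tests m and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and np.nanmin(p) < 0 or p.size and np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_deg(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with q <= alpha; adds an up/down direction from FC vs 1.

    ``results`` needs columns gene_id, effect, p, q and optionally fc
    (plus fc_lo/fc_hi).  Direction is "up" for FC > 1 (up-regulated in REST,
    or in females, by the fold-change conventions), "down" for FC < 1.
    """
    if results.empty:
        return results.assign(direction=pd.Series(dtype=str))
    out = results[results["q"] <= alpha].copy()
    if "fc" in out.columns:
        out["direction"] = np.where(out["fc"] > 1.0, "up", "down")
    return out.reset_index(drop=True)


def contrast_within_interaction(
    gate: pd.DataFrame,
    contrasts: pd.DataFrame,
    alpha_q: float = 0.05,
    alpha_p: float = 0.05,
) -> pd.DataFrame:
    """Two-stage contrast DEG rule.

    ``gate`` holds the gating term's q per gene (columns gene_id, q);
    ``contrasts`` the contrast results (gene_id, p, ...).  A gene is
    reported iff its gate q <= alpha_q AND its contrast p < alpha_p.
    """
    merged = contrasts.merge(
        gate[["gene_id", "q"]].rename(columns={"q": "gate_q"}), on="gene_id", how="inner"
    )
    keep = (merged["gate_q"] <= alpha_q) & (merged["p"] < alpha_p)
    out = merged[keep].copy()
    if "fc" in out.columns:
        out["direction"] = np.where(out["fc"] > 1.0, "up", "down")
    return out.reset_index(drop=True)


def venn_counts(deg_sets: dict) -> dict:
    """Disjoint region counts for up to three DEG sets.

    Keys of the result name the member sets joined by "&" (e.g. for sets
    A, B, C: "A", "B", "C", "A&B", "A&C", "B&C", "A&B&C"), each counting
    genes in exactly those sets.
    """
    names = list(deg_sets)
    if not 1 <= len(names) <= 3:
        raise ValueError("venn_counts supports 1-3 sets")
    sets = {k: set(v) for k, v in deg_sets.items()}
    universe = set().union(*sets.values())
    out = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for c in combo:
                inside &= sets[c]
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            out["&".join(combo)] = len(inside)
    return out


def volcano_table(
    results: pd.DataFrame, fc_clip: float = 5.0, q_clip: float = 1e-6
) -> pd.DataFrame:
    """Plot-ready volcano rows: X = FC, Y = -log10 q, extremes removed.

    Drops rows with FC < 1/fc_clip or FC > fc_clip or q < q_clip.
    """
    req = {"gene_id", "fc", "q"}
    if not req.issubset(results.columns):
        raise ValueError(f"volcano_table needs columns {sorted(req)}")
    keep = (
        (results["fc"] >= 1.0 / fc_clip)
        & (results["fc"] <= fc_clip)
        & (results["q"] >= q_clip)
    )
    out = results[keep].copy()
    out["x_fc"] = out["fc"]
    out["y_neglog10_q"] = -np.log10(out["q"])
    return out.reset_index(drop=True)
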