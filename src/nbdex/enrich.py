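"""Local over-representation analysis against a background gene list.

For each annotation term: observed = |DEG ∩ term|, expected =
|DEG| * |term| / |background|, fold enrichment = observed/expected, with a
two-sided Fisher's exact p-value from the 2x2 table

    [[observed, |DEG| - observed],
     [|term| - observed, |background| - |DEG| - |term| + observed]].

The sign is "+" when observed > expected (over-representation), "-"
otherwise.  P-values are reported unadjusted and flagged at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["Annotation", "read_gmt", "write_gmt", "overrepresentation"]


@dataclass
class Annotation:
    """Term -> gene-set mapping over a background gene universe."""

    terms: dict[str, set]
    background: set
    descriptions: dict[str, str] | None = None

    def __post_init__(self):
        self.background = set(self.background)
        clean = {}
        for term, genes in self.terms.items():
            gs = set(genes) & self.background
            if gs:
                clean[term] = gs
        self.terms = clean


def read_gmt(path) -> Annotation:
    """Read a GMT file (term <tab> description <tab> gene...)."""
    terms, desc, bg = {}, {}, set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, d, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            terms[term] = set(genes)
            desc[term] = d
            bg |= terms[term]
    return Annotation(terms=terms, background=bg, descriptions=desc)


def write_gmt(ann: Annotation, path) -> None:
    with open(path, "w") as fh:
        for term, genes in ann.terms.items():
            d = (ann.descriptions or {}).get(term, "")
            fh.write("\t".join([term, d, *sorted(genes)]) + "\n")


def overrepresentation(
    deg, ann: Annotation, min_term_size: int = 2, alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher-exact over-representation of DEG per annotation term.

    ``deg`` must be a subset of the annotation background.  Returns one row
    per term of size >= min_term_size, sorted by p, with columns term,
    n_term, n_deg_in_term, expected, fold_enrichment, direction, p,
    significant.
    """
    deg = set(deg)
    missing = deg - ann.background
    if missing:
        raise ValueError(f"DEG not in background: {sorted(missing)[:10]}")
    if len(ann.background) < 2:
        raise ValueError("background must contain at least 2 genes")
    N, K = len(ann.background), len(deg)
    rows = []
    for term, genes in ann.terms.items():
        M = len(genes)
        if M < min_term_size:
            continue
        obs = len(deg & genes)
        expected = K * M / N
        table = [[obs, K - obs], [M - obs, N - K - M + obs]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "term": term,
                "description": (ann.descriptions or {}).get(term, ""),
                "n_term": M,
                "n_deg_in_term": obs,
                "expected": expected,
                "fold_enrichment": obs / expected if expected > 0 else float("nan"),
                "direction": "+" if obs > expected else "-",
                "p": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "description",
            "n_term",
            "n_deg_in_term",
            "expected",
            "fold_enrichment",
            "direction",
            "p",
        ],
    )
    if not out.empty:
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
        out["significant"] = out["p"] < alpha
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out
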