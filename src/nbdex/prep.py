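"""Count-matrix I/O, low-count filtering, and TMM normalization.

A count matrix is a genes x samples pandas DataFrame of nonnegative
integers with unique gene ids as index and sample ids as columns.  The
sample design is a DataFrame with one row per sample.

The low-count filter removes genes whose total count is less than four
times the number of samples.  Normalization factors follow the canonical
trimmed-mean-of-M-values recipe: reference sample by upper-quartile
closeness to the mean, doubly trimmed (30% on M, 5% on A) precision-weighted
mean of log2 ratios over genes expressed in both samples, and a geometric
rescaling so the factors multiply to one.  The per-sample normalized library
size — used downstream as the model offset — is the raw library size
divided by the factor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "validate_counts",
    "filter_low_counts",
    "tmm_factors",
    "normalized_library_sizes",
    "attach_library_sizes",
]


def read_counts(path) -> pd.DataFrame:
    """Read a TSV count matrix (first column gene ids, header sample ids)."""
    cm = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(cm)
    return cm


def write_counts(cm: pd.DataFrame, path) -> None:
    cm.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def validate_counts(cm: pd.DataFrame) -> None:
    if cm.shape[0] == 0 or cm.shape[1] == 0:
        raise ValueError("empty count matrix")
    if not cm.index.is_unique:
        raise ValueError("gene ids are not unique")
    if not cm.columns.is_unique:
        raise ValueError("sample ids are not unique")
    vals = cm.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative counts")


def filter_low_counts(cm: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with total count >= 4 x number of samples (order preserved)."""
    validate_counts(cm)
    keep = cm.sum(axis=1) >= 4 * cm.shape[1]
    return cm.loc[keep]


def _quantile_ref(cm: np.ndarray, lib: np.ndarray) -> int:
    f75 = np.array([np.quantile(cm[:, j] / lib[j], 0.75) for j in range(cm.shape[1])])
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    cm: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: int | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factor per sample.

    M-values are computed over genes with nonzero count in both the sample
    and the reference (log of zero is undefined); the doubly trimmed,
    inverse-asymptotic-variance-weighted mean of M gives the log2 factor.
    Factors are rescaled to multiply to one.
    """
    validate_counts(cm)
    if cm.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    counts = cm.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(cm.columns[lib <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    if ref is None:
        ref = _quantile_ref(counts, lib)
    yr, Nr = counts[:, ref], lib[ref]
    factors = np.ones(cm.shape[1])
    for j in range(cm.shape[1]):
        if j == ref:
            continue
        y, N = counts[:, j], lib[j]
        both = (y > 0) & (yr > 0)
        if not both.any():
            warnings.warn(f"no co-expressed genes between sample {cm.columns[j]} and reference")
            continue
        p, pr = y[both] / N, yr[both] / Nr
        M = np.log2(p / pr)
        A = 0.5 * np.log2(p * pr)
        w = (N - y[both]) / (N * y[both]) + (Nr - yr[both]) / (Nr * yr[both])
        n = len(M)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        keep = (
            (rM >= np.floor(n * trim_m) + 1)
            & (rM <= n + 1 - (np.floor(n * trim_m) + 1))
            & (rA >= np.floor(n * trim_a) + 1)
            & (rA <= n + 1 - (np.floor(n * trim_a) + 1))
        )
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.columns, name="norm_factor")


def normalized_library_sizes(
    cm: pd.DataFrame, factors: pd.Series, convention: str = "divide"
) -> pd.Series:
    """Normalized library size per sample, the offset of the count models.

    ``convention="divide"`` (default) divides the raw library size by the
    TMM factor; ``"multiply"`` gives the usual effective library size
    (raw size times factor) instead.
    """
    factors = factors.reindex(cm.columns)
    if (factors <= 0).any() or factors.isna().any():
        raise ValueError("normalization factors must be positive for every sample")
    lib = cm.sum(axis=0).astype(float)
    if convention == "divide":
        L = lib / factors
    elif convention == "multiply":
        L = lib * factors
    else:
        raise ValueError("convention must be 'divide' or 'multiply'")
    return pd.Series(L, index=cm.columns, name="normalized_library_size")


def attach_library_sizes(
    design: pd.DataFrame, cm: pd.DataFrame, convention: str = "divide", **tmm_kw
) -> pd.DataFrame:
    """Add library_size, norm_factor and normalized_library_size columns."""
    factors = tmm_factors(cm, **tmm_kw)
    L = normalized_library_sizes(cm, factors, convention=convention)
    out = design.copy()
    out = out.set_index("sample_id") if "sample_id" in out.columns else out
    out["library_size"] = cm.sum(axis=0).astype(float)
    out["norm_factor"] = factors
    out["normalized_library_size"] = L
    return out.reset_index()
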