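"""Term tests, planned contrasts, and Satterthwaite denominator df.

Wald tests are formed from the fitted coefficient covariance.  The
denominator degrees of freedom come from the Satterthwaite moment-matching
recipe: a variance that is a linear combination ``sum_k a_k v_k`` of
independent variance estimates ``v_k`` with ``d_k`` degrees of freedom gets

    df = (sum_k a_k v_k)^2 / sum_k (a_k v_k)^2 / d_k .

For an independent-residual GLM fit the working model has one pooled
variance component, so the df reduce to the residual df ``n - p`` plus any
prior df contributed by empirical-Bayes dispersion squeezing.  For
CS/AR1 working-correlation fits the df are moment-matched over per-animal
score contributions to the contrast variance (each contributing one df),
reflecting that animals, not samples, are the independent replicates.

Planned contrasts over the four blood visits (0, 3, 6, 15 dpw):

* vaccination — mean of days 0, 3, 6 versus day 15: (1/3, 1/3, 1/3, -1);
* weaning — day 0 versus mean of days 3 and 6: (1, -1/2, -1/2, 0);

each also in an interaction version applying the vector with opposite sign
across the two diets.  Fold changes are ``exp(estimate)`` with 95% CI
``exp(estimate ± t_{df,0.975} * SE)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import NBFit
from .models import DesignInfo

__all__ = [
    "TermTest",
    "ContrastResult",
    "satterthwaite_df",
    "satterthwaite_df_fit",
    "test_term",
    "estimate_contrast",
    "diet_contrast_vector",
    "sex_contrast_vector",
    "time_contrast_vector",
    "VACCINATION_WEIGHTS",
    "WEANING_WEIGHTS",
]

# weights over the blood time levels in increasing dpw order (0, 3, 6, 15)
VACCINATION_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0, -1.0)
WEANING_WEIGHTS = (1.0, -0.5, -0.5, 0.0)


@dataclass
class TermTest:
    gene_id: str
    term: str
    statistic: float
    df_num: int
    df_den: float
    p: float


@dataclass
class ContrastResult:
    gene_id: str
    label: str
    estimate: float
    se: float
    statistic: float
    df_num: int
    df_den: float
    p: float
    fc: float
    fc_lo: float
    fc_hi: float


def satterthwaite_df(a, v, d) -> float:
    """Moment-matching df for the variance combination sum(a*v).

    ``a`` are the (nonnegative) combination coefficients, ``v`` the variance
    component estimates, ``d`` their degrees of freedom.  Degenerate input
    (zero total variance) floors the df at 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    d = np.asarray(d, dtype=float)
    total = float(np.sum(a * v))
    denom = float(np.sum((a * v) ** 2 / d))
    if total <= 0 or denom <= 0:
        warnings.warn("degenerate variance in Satterthwaite df; flooring at 1")
        return 1.0
    return total**2 / denom


def satterthwaite_df_fit(fit: NBFit, L: np.ndarray) -> float:
    """Denominator df for contrast (or contrast-set row) L under a fit.

    Independent-residual fits have a single pooled working variance
    component: df = n - p.  Working-correlation fits are moment-matched
    over per-animal contributions; invariant to rescaling L.
    """
    if getattr(fit, "structure", "IND") == "IND" or not hasattr(fit, "cluster_scores"):
        # Residual df of the working model, plus the prior df contributed by
        # empirical-Bayes dispersion squeezing (a squeezed dispersion behaves
        # like a variance estimate with residual + prior df, as in moderated
        # tests); prior df is 0 unless the fit records a squeeze.
        return float(max(fit.residual_df + getattr(fit, "df_prior", 0.0), 1))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    # per-cluster contribution of the (possibly multi-row) contrast variance
    contrib = np.array(
        [float(np.sum((L @ u) ** 2)) for u in fit.cluster_scores]
    )
    if contrib.sum() <= 0:
        warnings.warn("degenerate variance in Satterthwaite df; flooring at 1")
        return 1.0
    df = satterthwaite_df(np.ones_like(contrib), contrib, np.ones_like(contrib))
    return float(max(df, 1.0))


def test_term(fit: NBFit, term: str, gene_id: str = "") -> TermTest | None:
    """Wald F-test of all coefficients belonging to one model term.

    Returns None when the term is absent from the fitted model (e.g. the
    interaction was dropped by AIC selection).
    """
    info: DesignInfo = fit.design_info
    full_idx = info.term_columns(term)
    if not full_idx:
        return None
    # map through aliasing: positions of surviving columns in the fit
    name_by_full = [info.colnames[i] for i in full_idx]
    pos = [fit.colnames.index(nm) for nm in name_by_full if nm in fit.colnames]
    if not pos:
        return None
    beta = fit.beta[pos]
    V = fit.cov[np.ix_(pos, pos)]
    r = len(pos)
    try:
        stat = float(beta @ np.linalg.solve(V, beta)) / r
    except np.linalg.LinAlgError:
        stat = float(beta @ np.linalg.pinv(V) @ beta) / r
    L = np.zeros((r, len(fit.beta)))
    for i, j in enumerate(pos):
        L[i, j] = 1.0
    df_den = satterthwaite_df_fit(fit, L)
    p = float(stats.f.sf(stat, r, df_den))
    return TermTest(gene_id, term, stat, r, df_den, p)


def estimate_contrast(
    fit: NBFit, L: np.ndarray, label: str = "", gene_id: str = "", conf: float = 0.95
) -> ContrastResult:
    """1-df contrast: t statistic, Satterthwaite df, p, FC with CI."""
    L = np.asarray(L, dtype=float)
    if L.shape != fit.beta.shape:
        raise ValueError(
            f"contrast length {L.shape} does not match coefficients {fit.beta.shape}"
        )
    est = float(L @ fit.beta)
    var = float(L @ fit.cov @ L)
    if var <= 0:
        raise ValueError(f"contrast {label!r} is not estimable (zero variance)")
    se = np.sqrt(var)
    df = satterthwaite_df_fit(fit, L)
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.5 + conf / 2.0, df))
    return ContrastResult(
        gene_id=gene_id,
        label=label,
        estimate=est,
        se=se,
        statistic=t,
        df_num=1,
        df_den=df,
        p=p,
        fc=float(np.exp(est)),
        fc_lo=float(np.exp(est - tcrit * se)),
        fc_hi=float(np.exp(est + tcrit * se)),
    )


def _coef_space(fit: NBFit, full_vector: np.ndarray, info: DesignInfo) -> np.ndarray:
    """Project a contrast built on the full encoding onto the fitted columns."""
    out = np.zeros(len(fit.beta))
    for i, nm in enumerate(info.colnames):
        if abs(full_vector[i]) > 0:
            if nm not in fit.colnames:
                raise ValueError(f"contrast touches aliased column {nm!r}; not estimable")
            out[fit.colnames.index(nm)] = full_vector[i]
    return out


def diet_contrast_vector(fit: NBFit, other: str = "sex") -> np.ndarray:
    """Marginal REST-vs-CTRL effect, averaged over the other design factor."""
    info: DesignInfo = fit.design_info
    diets = info.levels["diet"]
    others = info.levels.get(other, [None])
    full = np.zeros(len(info.colnames))
    for lev in others:
        kw = {} if lev is None else {other: lev}
        full += (
            info.cell_row(diet=diets[-1], **kw) - info.cell_row(diet=diets[0], **kw)
        ) / len(others)
    return _coef_space(fit, full, info)


def sex_contrast_vector(fit: NBFit) -> np.ndarray:
    """Female-vs-male effect averaged over diets (FC > 1 means up in females)."""
    info: DesignInfo = fit.design_info
    sexes = info.levels["sex"]
    female = "heifer" if "heifer" in sexes else sexes[0]
    male = [s for s in sexes if s != female][0]
    diets = info.levels["diet"]
    full = np.zeros(len(info.colnames))
    for d in diets:
        full += (info.cell_row(sex=female, diet=d) - info.cell_row(sex=male, diet=d)) / len(
            diets
        )
    return _coef_space(fit, full, info)


def time_contrast_vector(
    fit: NBFit, weights, interaction: bool = False
) -> np.ndarray:
    """Planned contrast over time levels, optionally its diet interaction.

    ``weights`` align with the time levels in increasing dpw order and must
    sum to 0.  The main-effect version averages cells over diets; the
    interaction version applies the weights with opposite sign across the
    two diets (REST minus CTRL).
    """
    info: DesignInfo = fit.design_info
    times = info.levels["time"]
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(times):
        raise ValueError(f"{len(weights)} weights for {len(times)} time levels")
    if abs(weights.sum()) > 1e-9:
        raise ValueError("contrast weights must sum to 0")
    diets = info.levels["diet"]
    full = np.zeros(len(info.colnames))
    for w, t in zip(weights, times):
        if interaction:
            full += w * (info.cell_row(diet=diets[-1], time=t) - info.cell_row(diet=diets[0], time=t))
        else:
            for d in diets:
                full += w * info.cell_row(diet=d, time=t) / len(diets)
    return _coef_space(fit, full, info)
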