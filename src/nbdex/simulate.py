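"""Synthetic count data mirroring a 2x2 factorial muscle arm and a
longitudinal blood arm of a maternal-nutrition calf study.

Muscle: two maternal diets (CTRL, REST) x two sexes (steer, heifer), pens
nested in diet, sequencing batches, two service sires, RIN and
days-on-dietary-treatment covariates.  Blood: steers only, sampled at 0, 3,
6, and 15 days post weaning with within-animal dependence.

Counts are NB2 (variance mu + a*mu^2) with per-gene dispersion and log-scale
library-size offsets.  Longitudinal dependence uses a Gaussian copula: a
latent MVN with AR1/CS/IND correlation over visits, pushed through the NB
quantile function, which preserves exact NB marginals while inducing
controllable within-animal correlation.  AR1 lags are visit indices
(equally spaced), not day-valued gaps.

A configurable fraction of genes carries diet, sex, time, and interaction
effects with log fold changes drawn on the natural-log scale; the returned
truth table records every generating coefficient and a DE flag per effect
(flag true iff the corresponding coefficients are not all zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigurationError",
    "MuscleDesignConfig",
    "BloodDesignConfig",
    "CovariateConfig",
    "NuisanceConfig",
    "DispersionConfig",
    "EffectConfig",
    "SimulationConfig",
    "simulate_muscle_dataset",
    "simulate_blood_dataset",
    "simulate_annotation",
]

TIME_POINTS_DPW = (0, 3, 6, 15)


class ConfigurationError(ValueError):
    pass


@dataclass
class MuscleDesignConfig:
    n_per_diet_sex: int = 6  # 12 steers + 12 heifers total
    n_pens_per_diet: int = 5
    n_batches: int = 2
    n_sires: int = 2


@dataclass
class BloodDesignConfig:
    n_steers: int = 12
    time_points_dpw: tuple = TIME_POINTS_DPW
    correlation_structure: str = "AR1"
    rho: float = 0.3
    n_batches: int = 3
    n_sires: int = 2


@dataclass
class CovariateConfig:
    rin_range: tuple = (8.0, 10.0)  # samples below RIN 8 are excluded upstream
    dot_mean_sd: tuple = (40.0, 5.1)


@dataclass
class NuisanceConfig:
    """Magnitudes (log-scale SD) of non-treatment effects."""

    batch_sd: float = 0.1
    pen_sd: float = 0.05
    sire_sd: float = 0.05
    rin_slope_sd: float = 0.02
    dot_slope_sd: float = 0.005

    @classmethod
    def none(cls) -> "NuisanceConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class DispersionConfig:
    global_a: float = 0.1
    genewise_spread: float = 0.3  # SD of log-dispersion around log(global_a)


@dataclass
class EffectConfig:
    prop_de_diet: float = 0.05
    prop_de_sex: float = 0.05
    prop_de_time: float = 0.10
    prop_de_interaction: float = 0.02
    logfc_distribution: tuple = (0.0, 0.5)  # natural-log scale


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    muscle_design: MuscleDesignConfig = field(default_factory=MuscleDesignConfig)
    blood_design: BloodDesignConfig = field(default_factory=BloodDesignConfig)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    library_size_range: tuple = (1.0e6, 2.0e6)
    dispersion: DispersionConfig = field(default_factory=DispersionConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    drop_one_sample: bool = False  # mirror the RIN-based exclusions
    seed: int = 0

    def validate(self) -> None:
        e = self.effects
        for name in ("prop_de_diet", "prop_de_sex", "prop_de_time", "prop_de_interaction"):
            v = getattr(e, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        b = self.blood_design
        tp = tuple(b.time_points_dpw)
        if len(tp) < 2 or any(t2 <= t1 for t1, t2 in zip(tp, tp[1:])):
            raise ConfigurationError("time points must be >=2 and strictly increasing")
        if not 0.0 <= b.rho < 1.0:
            raise ConfigurationError(f"rho={b.rho} outside [0, 1)")
        if b.correlation_structure not in ("AR1", "CS", "IND"):
            raise ConfigurationError(f"unknown structure {b.correlation_structure!r}")
        if self.dispersion.global_a <= 0:
            raise ConfigurationError("global dispersion must be positive")
        if self.muscle_design.n_pens_per_diet < 2:
            raise ConfigurationError(
                "need >=2 pens per diet: a single pen is fully confounded with "
                "diet and the reduced-model comparison is not representable"
            )
        if self.library_size_range[0] <= 0 or self.library_size_range[1] < self.library_size_range[0]:
            raise ConfigurationError("invalid library_size_range")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _baseline_abundance(n_genes: int, rng) -> np.ndarray:
    w = np.exp(rng.normal(0.0, 1.5, size=n_genes))
    return w / w.sum()


def _gene_dispersions(cfg: SimulationConfig, rng) -> np.ndarray:
    d = cfg.dispersion
    if d.genewise_spread == 0:
        return np.full(cfg.n_genes, d.global_a)
    return np.exp(rng.normal(np.log(d.global_a), d.genewise_spread, size=cfg.n_genes))


def _draw_lfc(rng, n, dist) -> np.ndarray:
    mean, sd = dist
    x = rng.normal(mean, sd, size=n)
    x[x == 0.0] = sd  # measure-zero guard: flags must imply nonzero effect
    return x


def _nb_counts(rng, mu: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Independent NB2 draws via the gamma-Poisson mixture."""
    a = np.broadcast_to(np.asarray(a, dtype=float)[:, None], mu.shape)
    lam = rng.gamma(shape=1.0 / a, scale=a * mu)
    return rng.poisson(lam)


def latent_correlation(structure: str, rho: float, n_times: int) -> np.ndarray:
    idx = np.arange(n_times)
    if structure == "IND" or rho == 0.0:
        return np.eye(n_times)
    if structure == "CS":
        R = np.full((n_times, n_times), rho)
        np.fill_diagonal(R, 1.0)
        return R
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_muscle_dataset(config: SimulationConfig):
    """Simulate the factorial muscle arm.

    Returns (counts DataFrame genes x samples, design DataFrame, truth
    DataFrame).  Counts are NB with mean exp(design effects + log library
    size) and variance mu + a*mu^2.
    """
    config.validate()
    rng = _rng(config.seed)
    m, cov, nui, eff = config.muscle_design, config.covariates, config.nuisance, config.effects
    G = config.n_genes

    rows = []
    k = 0
    for diet in ("CTRL", "REST"):
        pens = [f"{diet}_pen{i+1}" for i in range(m.n_pens_per_diet)]
        for sex in ("steer", "heifer"):
            for i in range(m.n_per_diet_sex):
                rows.append(
                    {
                        "sample_id": f"M{k+1:03d}",
                        "animal_id": f"calf{k+1:03d}",
                        "diet": diet,
                        "sex": sex,
                        "pen": pens[(i + (0 if sex == "steer" else m.n_per_diet_sex)) % len(pens)],
                        "batch": f"batch{(k % m.n_batches) + 1}",
                        "sire": f"sire{rng.integers(m.n_sires) + 1}",
                        "rin": rng.uniform(*cov.rin_range),
                        "dot": rng.normal(*cov.dot_mean_sd),
                    }
                )
                k += 1
    design = pd.DataFrame(rows)
    if config.drop_one_sample:
        design = design.drop(index=rng.integers(len(design))).reset_index(drop=True)
    n = len(design)

    rel = _baseline_abundance(G, rng)
    a = _gene_dispersions(config, rng)
    de_diet = rng.random(G) < eff.prop_de_diet
    de_sex = rng.random(G) < eff.prop_de_sex
    de_int = rng.random(G) < eff.prop_de_interaction
    lfc_diet = np.where(de_diet, _draw_lfc(rng, G, eff.logfc_distribution), 0.0)
    lfc_sex = np.where(de_sex, _draw_lfc(rng, G, eff.logfc_distribution), 0.0)
    lfc_int = np.where(de_int, _draw_lfc(rng, G, eff.logfc_distribution), 0.0)

    batch_eff = {
        b: rng.normal(0, nui.batch_sd, G) if j > 0 else np.zeros(G)
        for j, b in enumerate(sorted(design["batch"].unique()))
    }
    pen_eff = {p: rng.normal(0, nui.pen_sd, G) for p in sorted(design["pen"].unique())}
    sire_eff = {
        s: rng.normal(0, nui.sire_sd, G) if j > 0 else np.zeros(G)
        for j, s in enumerate(sorted(design["sire"].unique()))
    }
    rin_slope = rng.normal(0, nui.rin_slope_sd, G)
    dot_slope = rng.normal(0, nui.dot_slope_sd, G)

    L = rng.uniform(*config.library_size_range, size=n)
    rin_c = design["rin"].to_numpy() - design["rin"].mean()
    dot_c = design["dot"].to_numpy() - design["dot"].mean()
    is_rest = (design["diet"] == "REST").to_numpy(dtype=float)
    is_heifer = (design["sex"] == "heifer").to_numpy(dtype=float)

    log_mu = (
        np.log(rel)[:, None]
        + np.log(L)[None, :]
        + np.outer(lfc_diet, is_rest)
        + np.outer(lfc_sex, is_heifer)
        + np.outer(lfc_int, is_rest * is_heifer)
        + np.outer(rin_slope, rin_c)
        + np.outer(dot_slope, dot_c)
    )
    for j, b in enumerate(design["batch"]):
        log_mu[:, j] += batch_eff[b] + pen_eff[design["pen"].iloc[j]] + sire_eff[design["sire"].iloc[j]]

    counts = _nb_counts(rng, np.exp(log_mu), a)
    gene_ids = [f"gene{i+1:05d}" for i in range(G)]
    cm = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=design["sample_id"])

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "dispersion": a,
            "de_diet": lfc_diet != 0.0,
            "de_sex": lfc_sex != 0.0,
            "de_interaction": lfc_int != 0.0,
            "lfc_diet": lfc_diet,
            "lfc_sex": lfc_sex,
            "lfc_interaction": lfc_int,
        }
    )
    truth["model"] = np.where(truth["de_interaction"], "diet*sex", np.where(truth["de_diet"] | truth["de_sex"], "main", "null"))
    design = design.assign(library_size=cm.sum(axis=0).to_numpy())
    return cm, design, truth


def simulate_blood_dataset(config: SimulationConfig):
    """Simulate the longitudinal blood arm (steers at 0/3/6/15 dpw).

    Within-animal dependence comes from a Gaussian copula on visit indices;
    marginals are exact NB2 with the per-gene dispersion.
    """
    config.validate()
    rng = _rng(config.seed + 1)
    b, cov, nui, eff = config.blood_design, config.covariates, config.nuisance, config.effects
    G = config.n_genes
    times = tuple(b.time_points_dpw)
    T = len(times)

    rows = []
    for k in range(b.n_steers):
        diet = "CTRL" if k < b.n_steers // 2 else "REST"
        animal = f"steer{k+1:02d}"
        rin0 = rng.uniform(*cov.rin_range)
        dot = rng.normal(*cov.dot_mean_sd)
        sire = f"sire{rng.integers(b.n_sires) + 1}"
        pen = f"{diet}_pen{(k % 5) + 1}"
        for v, t in enumerate(times):
            rows.append(
                {
                    "sample_id": f"B{k+1:02d}_t{t}",
                    "animal_id": animal,
                    "diet": diet,
                    "sex": "steer",
                    "pen": pen,
                    "batch": f"batch{rng.integers(b.n_batches) + 1}",
                    "sire": sire,
                    "rin": np.clip(rin0 + rng.normal(0, 0.2), *cov.rin_range),
                    "dot": dot,
                    "time_dpw": t,
                    "visit": v,
                }
            )
    design = pd.DataFrame(rows)
    if config.drop_one_sample:
        design = design.drop(index=rng.integers(len(design))).reset_index(drop=True)
    n = len(design)

    rel = _baseline_abundance(G, rng)
    a = _gene_dispersions(config, rng)
    de_diet = rng.random(G) < eff.prop_de_diet
    de_time = rng.random(G) < eff.prop_de_time
    de_int = rng.random(G) < eff.prop_de_interaction
    lfc_diet = np.where(de_diet, _draw_lfc(rng, G, eff.logfc_distribution), 0.0)
    lfc_time = np.where(de_time[:, None], _draw_lfc(rng, G * (T - 1), eff.logfc_distribution).reshape(G, T - 1), 0.0)
    lfc_int = np.where(de_int[:, None], _draw_lfc(rng, G * (T - 1), eff.logfc_distribution).reshape(G, T - 1), 0.0)

    batch_eff = {
        bt: rng.normal(0, nui.batch_sd, G) if j > 0 else np.zeros(G)
        for j, bt in enumerate(sorted(design["batch"].unique()))
    }
    sire_eff = {
        s: rng.normal(0, nui.sire_sd, G) if j > 0 else np.zeros(G)
        for j, s in enumerate(sorted(design["sire"].unique()))
    }
    rin_slope = rng.normal(0, nui.rin_slope_sd, G)
    dot_slope = rng.normal(0, nui.dot_slope_sd, G)

    L = rng.uniform(*config.library_size_range, size=n)
    rin_c = design["rin"].to_numpy() - design["rin"].mean()
    dot_c = design["dot"].to_numpy() - design["dot"].mean()
    is_rest = (design["diet"] == "REST").to_numpy(dtype=float)
    visit = design["visit"].to_numpy()

    log_mu = (
        np.log(rel)[:, None]
        + np.log(L)[None, :]
        + np.outer(lfc_diet, is_rest)
        + np.outer(rin_slope, rin_c)
        + np.outer(dot_slope, dot_c)
    )
    for v in range(1, T):
        sel = (visit == v).astype(float)
        log_mu += np.outer(lfc_time[:, v - 1], sel)
        log_mu += np.outer(lfc_int[:, v - 1], sel * is_rest)
    for j in range(n):
        log_mu[:, j] += batch_eff[design["batch"].iloc[j]] + sire_eff[design["sire"].iloc[j]]
    mu = np.exp(log_mu)

    # Gaussian copula over visits within each animal
    R = latent_correlation(b.correlation_structure, b.rho, T)
    chol = np.linalg.cholesky(R)
    counts = np.empty((G, n), dtype=np.int64)
    animals = design["animal_id"].unique()
    for animal in animals:
        idx = np.flatnonzero((design["animal_id"] == animal).to_numpy())
        vis = visit[idx]
        z = rng.standard_normal((G, T)) @ chol.T
        u = stats.norm.cdf(z[:, vis])
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        r_g = (1.0 / a)[:, None]
        p = 1.0 / (1.0 + a[:, None] * mu[:, idx])
        counts[:, idx] = stats.nbinom.ppf(u, r_g, p).astype(np.int64)

    gene_ids = [f"gene{i+1:05d}" for i in range(G)]
    cm = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=design["sample_id"])
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "dispersion": a,
            "de_diet": lfc_diet != 0.0,
            "de_time": de_time & (np.abs(lfc_time).sum(axis=1) > 0),
            "de_interaction": de_int & (np.abs(lfc_int).sum(axis=1) > 0),
            "lfc_diet": lfc_diet,
        }
    )
    for v, t in enumerate(times[1:], start=1):
        truth[f"lfc_time_{t}"] = lfc_time[:, v - 1]
        truth[f"lfc_int_{t}"] = lfc_int[:, v - 1]
    truth["model"] = np.where(
        truth["de_interaction"], "diet*time", np.where(truth["de_diet"] | truth["de_time"], "main", "null")
    )
    design = design.assign(library_size=cm.sum(axis=0).to_numpy())
    return cm, design, truth


def simulate_annotation(
    gene_ids,
    n_terms: int = 20,
    term_size_range: tuple = (5, 50),
    seed: int = 0,
) -> dict[str, set]:
    """Toy term -> gene-set map over a background list, for enrichment tests."""
    rng = _rng(seed)
    gene_ids = list(gene_ids)
    ann = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(gene_ids))
        ann[f"TERM{t+1:04d}"] = set(rng.choice(gene_ids, size=size, replace=False))
    return ann
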