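"""End-to-end analysis arms: filter -> TMM -> dispersions -> per-gene AIC
model selection -> term tests and planned contrasts -> FDR.

The muscle arm fits four independent-residual NB candidates per gene (full
model; minus pen; minus diet-by-sex interaction; minus both) and tests the
diet, sex, and interaction terms.  The blood arm fits six candidates (with
and without the diet-by-time interaction, each under IND/CS/AR1 working
residual correlation), tests diet, time, and interaction, and evaluates the
two planned 1-df contrasts (weaning, vaccination) and their diet
interactions.  q-values are computed per term across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import NBFit, estimate_dispersions
from .inference import (
    VACCINATION_WEIGHTS,
    WEANING_WEIGHTS,
    diet_contrast_vector,
    estimate_contrast,
    sex_contrast_vector,
    test_term,
    time_contrast_vector,
)
from .models import (
    BLOOD_FULL_TERMS,
    MUSCLE_FULL_TERMS,
    DesignInfo,
    blood_candidates,
    center_covariates,
    fit_candidates,
    muscle_candidates,
    select_model,
)
from .prep import attach_library_sizes, filter_low_counts
from .summarize import bh_adjust

__all__ = ["ArmResults", "prepare", "run_muscle_arm", "run_blood_arm"]


@dataclass
class ArmResults:
    """Fitted arm: per-gene chosen fits plus long-format test results."""

    results: pd.DataFrame  # gene_id, effect, p, q, fc, fc_lo, fc_hi, ...
    fits: dict = field(default_factory=dict)  # gene_id -> NBFit (selected)
    models: pd.DataFrame | None = None  # gene_id, model label, aic, dispersion
    global_dispersion: float = float("nan")
    counts: pd.DataFrame | None = None
    design: pd.DataFrame | None = None

    def effect(self, name: str) -> pd.DataFrame:
        return self.results[self.results["effect"] == name].reset_index(drop=True)

    def deg_ids(self, name: str, alpha: float = 0.05) -> set:
        sub = self.effect(name)
        return set(sub.loc[sub["q"] <= alpha, "gene_id"])


def prepare(cm: pd.DataFrame, design: pd.DataFrame, convention: str = "divide"):
    """Low-count filter, TMM offsets, centered covariates."""
    cm = filter_low_counts(cm)
    design = attach_library_sizes(design, cm, convention=convention)
    design = center_covariates(design)
    offset = np.log(design["normalized_library_size"].to_numpy(dtype=float))
    return cm, design, offset


def _finalize(records, contrast_records, fits, model_rows, global_a, cm, design):
    res = pd.DataFrame(records)
    if not res.empty:
        res["q"] = np.nan
        for eff in res["effect"].unique():
            m = res["effect"] == eff
            res.loc[m, "q"] = bh_adjust(res.loc[m, "p"].to_numpy())
    con = pd.DataFrame(contrast_records)
    out = pd.concat([res, con], ignore_index=True) if len(con) else res
    return ArmResults(
        results=out,
        fits=fits,
        models=pd.DataFrame(model_rows),
        global_dispersion=global_a,
        counts=cm,
        design=design,
    )


def run_muscle_arm(
    cm: pd.DataFrame,
    design: pd.DataFrame,
    prior_df: float = 10.0,
    convention: str = "divide",
) -> ArmResults:
    cm, design, offset = prepare(cm, design, convention)
    full_info = DesignInfo.from_frame(design, MUSCLE_FULL_TERMS)
    X_full = full_info.encode(design)
    disp, global_a, _, _ = estimate_dispersions(
        cm.to_numpy(dtype=float), X_full, offset, prior_df=prior_df
    )
    specs = muscle_candidates()
    infos: dict = {}
    records, contrast_records, model_rows = [], [], []
    fits: dict[str, NBFit] = {}
    for g, gene in enumerate(cm.index):
        y = cm.iloc[g].to_numpy(dtype=float)
        cand = fit_candidates(y, design, offset, disp[g], specs, infos)
        try:
            spec, fit = select_model(cand)
        except ValueError:
            model_rows.append({"gene_id": gene, "model": "failed", "aic": np.nan, "dispersion": disp[g]})
            continue
        fit.df_prior = min(prior_df, 1e6)  # squeeze credit in Satterthwaite df
        fits[gene] = fit
        model_rows.append(
            {"gene_id": gene, "model": spec.label, "aic": fit.aic, "dispersion": disp[g]}
        )
        for term, effect in (("diet", "diet"), ("sex", "sex"), ("diet:sex", "interaction")):
            tt = test_term(fit, term, gene)
            rec = {"gene_id": gene, "effect": effect, "model": spec.label}
            if tt is None:
                rec.update({"p": np.nan, "statistic": np.nan, "df_den": np.nan})
            else:
                rec.update({"p": tt.p, "statistic": tt.statistic, "df_den": tt.df_den})
            if effect in ("diet", "sex") and tt is not None:
                vec = diet_contrast_vector(fit, other="sex") if effect == "diet" else sex_contrast_vector(fit)
                cr = estimate_contrast(fit, vec, label=effect, gene_id=gene)
                rec.update({"fc": cr.fc, "fc_lo": cr.fc_lo, "fc_hi": cr.fc_hi, "estimate": cr.estimate, "se": cr.se})
            records.append(rec)
    return _finalize(records, contrast_records, fits, model_rows, global_a, cm, design)


def run_blood_arm(
    cm: pd.DataFrame,
    design: pd.DataFrame,
    prior_df: float = 10.0,
    convention: str = "divide",
) -> ArmResults:
    cm, design, offset = prepare(cm, design, convention)
    design = design.copy()
    if "time" not in design.columns:
        design["time"] = design["time_dpw"].astype(str)
    full_info = DesignInfo.from_frame(design, BLOOD_FULL_TERMS)
    X_full = full_info.encode(design)
    disp, global_a, _, _ = estimate_dispersions(
        cm.to_numpy(dtype=float), X_full, offset, prior_df=prior_df
    )
    specs = blood_candidates(group="animal_id")
    infos: dict = {}
    records, contrast_records, model_rows = [], [], []
    fits: dict[str, NBFit] = {}
    for g, gene in enumerate(cm.index):
        y = cm.iloc[g].to_numpy(dtype=float)
        cand = fit_candidates(y, design, offset, disp[g], specs, infos)
        try:
            spec, fit = select_model(cand)
        except ValueError:
            model_rows.append({"gene_id": gene, "model": "failed", "aic": np.nan, "dispersion": disp[g]})
            continue
        fit.df_prior = min(prior_df, 1e6)
        fits[gene] = fit
        model_rows.append(
            {
                "gene_id": gene,
                "model": spec.label,
                "aic": fit.aic,
                "dispersion": disp[g],
                "structure": spec.structure,
                "rho": getattr(fit, "rho", 0.0),
            }
        )
        for term, effect in (("diet", "diet"), ("time", "time"), ("diet:time", "interaction")):
            tt = test_term(fit, term, gene)
            rec = {"gene_id": gene, "effect": effect, "model": spec.label}
            if tt is None:
                rec.update({"p": np.nan, "statistic": np.nan, "df_den": np.nan})
            else:
                rec.update({"p": tt.p, "statistic": tt.statistic, "df_den": tt.df_den})
            if effect == "diet" and tt is not None:
                vec = diet_contrast_vector(fit, other="time")
                cr = estimate_contrast(fit, vec, label="diet", gene_id=gene)
                rec.update({"fc": cr.fc, "fc_lo": cr.fc_lo, "fc_hi": cr.fc_hi, "estimate": cr.estimate, "se": cr.se})
            records.append(rec)
        for label, weights, interaction in (
            ("weaning", WEANING_WEIGHTS, False),
            ("vaccination", VACCINATION_WEIGHTS, False),
            ("weaning_x_diet", WEANING_WEIGHTS, True),
            ("vaccination_x_diet", VACCINATION_WEIGHTS, True),
        ):
            rec = {"gene_id": gene, "effect": label, "model": spec.label}
            try:
                vec = time_contrast_vector(fit, weights, interaction=interaction)
                if interaction and not np.any(vec):
                    raise ValueError("interaction absent from selected model")
                cr = estimate_contrast(fit, vec, label=label, gene_id=gene)
                rec.update(
                    {
                        "p": cr.p,
                        "statistic": cr.statistic,
                        "df_den": cr.df_den,
                        "fc": cr.fc,
                        "fc_lo": cr.fc_lo,
                        "fc_hi": cr.fc_hi,
                        "estimate": cr.estimate,
                        "se": cr.se,
                    }
                )
            except ValueError:
                rec.update({"p": np.nan})
            contrast_records.append(rec)
    return _finalize(records, contrast_records, fits, model_rows, global_a, cm, design)
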