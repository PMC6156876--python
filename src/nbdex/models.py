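"""Design matrices, candidate model sets, and AIC model selection.

The muscle model has fixed effects of diet, sex, their interaction, batch
(sequencing lane), pen (nested in diet), service sire, and centered RIN and
days-on-dietary-treatment covariates, with the log TMM-normalized library
size as offset.  Reduced muscle candidates drop pen and/or the interaction
(4 candidates).  The blood model replaces sex with time (4 visits) and drops
pen; candidates cross {with, without interaction} with the three residual
structures {IND, CS, AR1} (6 candidates).  The per-gene final model is the
converged candidate with minimal (pseudo-)AIC, ties broken toward fewer
parameters, then by candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gee import fit_nb_repeated
from .glm import NBFit, fit_nb_glm

__all__ = [
    "DesignInfo",
    "ModelSpec",
    "muscle_candidates",
    "blood_candidates",
    "fit_candidates",
    "select_model",
    "center_covariates",
]

CONTINUOUS = {"rin_c", "dot_c"}


def center_covariates(design: pd.DataFrame) -> pd.DataFrame:
    """Add sample-mean-centered RIN and DOT columns (R - Rbar, DOT - DOTbar)."""
    out = design.copy()
    if "rin" in out:
        out["rin_c"] = out["rin"] - out["rin"].mean()
    if "dot" in out:
        out["dot_c"] = out["dot"] - out["dot"].mean()
    return out


@dataclass
class DesignInfo:
    """Treatment-coded design encoder with frozen factor levels.

    Factor terms are dummy-coded dropping the first level; interaction terms
    ("a:b") are products of the parents' dummy sets.  Continuous terms are
    passed through.  Levels are frozen at construction so arbitrary factor
    combinations (e.g. diet-by-time cells) can be encoded consistently later.
    """

    terms: list[str]
    levels: dict = field(default_factory=dict)
    colnames: list[str] = field(default_factory=list)

    @classmethod
    def from_frame(cls, design: pd.DataFrame, terms: list[str]) -> "DesignInfo":
        for t in terms:
            for f in t.split(":"):
                if f != "1" and f not in design.columns:
                    raise ValueError(f"term {t!r}: column {f!r} not in design")
            if ":" in t:
                parents = t.split(":")
                for p in parents:
                    if p not in terms:
                        raise ValueError(f"interaction {t!r} requires main effect {p!r}")
        levels = {}
        for t in terms:
            for f in t.split(":"):
                if f != "1" and f not in CONTINUOUS and f not in levels:
                    vals = list(pd.unique(design[f].astype(str)))
                    try:
                        vals = sorted(vals, key=float)  # numeric levels (time) in order
                    except ValueError:
                        vals = sorted(vals)
                    levels[f] = vals
        info = cls(terms=list(terms), levels=levels)
        info.colnames = info._encode(design, collect_names=True)[1]
        return info

    def _factor_dummies(self, col: pd.Series, factor: str):
        lv = self.levels[factor]
        mats, names = [], []
        vals = col.astype(str).to_numpy()
        for level in lv[1:]:
            mats.append((vals == level).astype(float))
            names.append(f"{factor}[{level}]")
        return mats, names

    def _encode(self, design: pd.DataFrame, collect_names: bool = False):
        n = len(design)
        cols, names = [np.ones(n)], ["Intercept"]
        for t in self.terms:
            if t == "1":
                continue
            parts = t.split(":")
            part_mats, part_names = [], []
            for f in parts:
                if f in CONTINUOUS or (f not in self.levels):
                    part_mats.append([design[f].to_numpy(dtype=float)])
                    part_names.append([f])
                else:
                    m, nm = self._factor_dummies(design[f], f)
                    part_mats.append(m)
                    part_names.append(nm)
            # cartesian product across parts
            prod_mats, prod_names = part_mats[0], part_names[0]
            for m2, n2 in zip(part_mats[1:], part_names[1:]):
                prod_mats = [a * b for a in prod_mats for b in m2]
                prod_names = [f"{a}:{b}" for a in prod_names for b in n2]
            cols.extend(prod_mats)
            names.extend(prod_names)
        X = np.column_stack(cols) if cols else np.empty((n, 0))
        return X, names

    def encode(self, design: pd.DataFrame) -> np.ndarray:
        X, names = self._encode(design)
        assert names == self.colnames
        return X

    def term_columns(self, term: str) -> list[int]:
        """Column indices (into the full encoding) belonging to one term."""
        if term == "1":
            return [0]
        parts = term.split(":")
        idx = []
        for i, name in enumerate(self.colnames):
            if name == "Intercept":
                continue
            facs = [p.split("[")[0] for p in name.split(":")]
            if sorted(facs) == sorted(parts):
                idx.append(i)
        return idx

    def cell_row(self, **factor_values) -> np.ndarray:
        """Encode a single synthetic observation at the given factor levels.

        Unspecified factors sit at their reference level and continuous
        covariates at 0 (their centered mean), so nuisance columns cancel in
        any contrast whose weights sum to zero.
        """
        row = {}
        for f, lv in self.levels.items():
            row[f] = factor_values.get(f, lv[0])
        for f in CONTINUOUS:
            row[f] = factor_values.get(f, 0.0)
        for f, v in factor_values.items():
            row[f] = v
        return self._encode(pd.DataFrame([row]))[0][0]


@dataclass
class ModelSpec:
    """One candidate model: mean terms plus a residual-correlation structure."""

    terms: list[str]
    structure: str = "IND"
    group: str | None = None
    label: str = ""

    def __post_init__(self):
        if self.structure in ("CS", "AR1") and self.group is None:
            raise ValueError("CS/AR1 structures require a grouping variable")
        for t in self.terms:
            if ":" in t:
                for p in t.split(":"):
                    if p not in self.terms:
                        raise ValueError(
                            f"interaction {t!r} present without main effect {p!r}"
                        )
        if not self.label:
            self.label = "+".join(self.terms) + f"|{self.structure}"


MUSCLE_FULL_TERMS = ["diet", "sex", "diet:sex", "batch", "pen", "rin_c", "dot_c", "sire"]
BLOOD_FULL_TERMS = ["diet", "time", "diet:time", "batch", "rin_c", "dot_c", "sire"]


def muscle_candidates(extra_terms: list[str] | None = None) -> list[ModelSpec]:
    """Full muscle model plus reduced models dropping pen and/or interaction."""
    base = list(MUSCLE_FULL_TERMS) if extra_terms is None else list(extra_terms)
    out = []
    for drop_pen in (False, True):
        for drop_int in (False, True):
            terms = [
                t
                for t in base
                if not (drop_pen and t == "pen") and not (drop_int and t == "diet:sex")
            ]
            tag = "full" if not (drop_pen or drop_int) else (
                "-pen-int" if drop_pen and drop_int else ("-pen" if drop_pen else "-int")
            )
            out.append(ModelSpec(terms=terms, structure="IND", label=f"muscle:{tag}"))
    return out


def blood_candidates(group: str = "animal_id") -> list[ModelSpec]:
    """{full, no-interaction} x {IND, CS, AR1} blood candidates."""
    out = []
    for drop_int in (False, True):
        terms = [t for t in BLOOD_FULL_TERMS if not (drop_int and t == "diet:time")]
        tag = "full" if not drop_int else "-int"
        for st in ("IND", "CS", "AR1"):
            out.append(
                ModelSpec(terms=terms, structure=st, group=group, label=f"blood:{tag}|{st}")
            )
    return out


def fit_candidates(
    y,
    design: pd.DataFrame,
    offset,
    a: float,
    specs: list[ModelSpec],
    infos: dict[str, DesignInfo] | None = None,
) -> list[tuple[ModelSpec, NBFit | None]]:
    """Fit every candidate; non-converged/failed candidates yield None."""
    infos = infos or {}
    out = []
    for spec in specs:
        info = infos.get(spec.label)
        if info is None:
            info = DesignInfo.from_frame(design, spec.terms)
            infos[spec.label] = info
        X = info.encode(design)
        try:
            if spec.structure == "IND":
                fit = fit_nb_glm(y, X, offset, a, colnames=info.colnames)
            else:
                fit = fit_nb_repeated(
                    y,
                    X,
                    offset,
                    a,
                    structure=spec.structure,
                    animal_id=design[spec.group].to_numpy(),
                    visit=design["visit"].to_numpy() if "visit" in design else None,
                    colnames=info.colnames,
                )
            fit.design_info = info
            fit.spec = spec
        except Exception:
            fit = None
        out.append((spec, fit))
    return out


def select_model(fits: list[tuple[ModelSpec, NBFit | None]]):
    """Minimal-AIC converged candidate; ties to fewer parameters, then order.

    Raises ValueError if no candidate converged.
    """
    best = None
    for order, (spec, fit) in enumerate(fits):
        if fit is None or not fit.converged or not np.isfinite(fit.aic):
            continue
        key = (round(fit.aic, 10), fit.n_params, order)
        if best is None or key < best[0]:
            best = (key, spec, fit)
    if best is None:
        raise ValueError("no converged candidate model")
    return best[1], best[2]
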