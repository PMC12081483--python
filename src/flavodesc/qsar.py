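"""Descriptor-based QSAR: exhaustive-subset multiple linear regression,
adjusted R-squared model selection, and leave-one-out (LOO) Q^2 validation.

With a handful of molecules and thousands of candidate descriptors, small
linear models are found by exhaustively scoring every descriptor subset of
a fixed size (deterministic, feasible for <= 3 terms) and keeping the subset
with the best adjusted R^2. At the sample sizes typical of this kind of
study (n ~ 7, 3-term models) adjusted R^2 near 1 is expected from
overfitting alone, so a degrees-of-freedom warning accompanies such fits
and LOO Q^2 = 1 - PRESS/TSS is the honest validation statistic.

The three published GPER-binding models ship as named built-ins
(:data:`MODEL_1`, :data:`MODEL_2`, :data:`MODEL_3`) for evaluation on new
descriptor values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegreesOfFreedomWarning(UserWarning):
    """Fit has too few residual degrees of freedom to be trusted."""


@dataclass(frozen=True)
class QsarModel:
    """Linear model: prediction = intercept + sum(coef * descriptor)."""

    intercept: float
    terms: tuple[tuple[str, float], ...]
    fit_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor names in model terms")

    @property
    def descriptor_names(self) -> list[str]:
        return [n for n, _ in self.terms]

    def predict(self, values: dict[str, float]) -> float:
        return apply_model(self, values)


def apply_model(model: QsarModel, values: dict[str, float]) -> float:
    """Evaluate a linear QSAR model on supplied descriptor values
    (kcal/mol for the built-in binding-energy models)."""
    out = model.intercept
    for name, coef in model.terms:
        if name not in values:
            raise KeyError(f"missing descriptor {name!r}")
        out += coef * values[name]
    return float(out)


#: published GPER-binding MMGBSA models (response in kcal/mol)
MODEL_1 = QsarModel(
    416.81467,
    (("RNCG", -205.30923), ("MWC05", -54.65308), ("ATSC6p", 2.71864)),
    {"source": "2D/3D descriptor set A", "adjusted_r2_reported": 0.9998},
)
MODEL_2 = QsarModel(
    -19.18640,
    (("TDB10m", -0.00494), ("RDF105p", -7.04049), ("RDF115e", 1.64234)),
    {"source": "3D descriptor set B", "adjusted_r2_reported": 0.9970},
)
MODEL_3 = QsarModel(
    -10.90223,
    (("ATS7s", -0.04025), ("ATSC6p", 1.52915), ("SssCH2", 2.64078)),
    {"source": "2D descriptor set B", "adjusted_r2_reported": 0.9999},
)
BUILTIN_MODELS = {"model1": MODEL_1, "model2": MODEL_2, "model3": MODEL_3}


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (coefs incl. intercept, r2, rank_ok)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return None
    resid = y - design @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return coef, r2, resid


def fit_mlr(
    descriptors: pd.DataFrame, response, subset_size: int = 3
) -> QsarModel:
    """Exhaustive best-subset OLS of the response on ``subset_size``
    descriptors, ranked by adjusted R^2.

    Collinear subsets are skipped with a warning; ties in adjusted R^2 break
    toward lexicographically smaller descriptor-name tuples (the candidate
    enumeration order over sorted names).
    """
    y = np.asarray(response, float)
    n, p_all = descriptors.shape
    if subset_size < 1 or subset_size > 3:
        raise ValueError("subset_size must be between 1 and 3")
    if n < subset_size + 2:
        raise ValueError(
            f"need at least subset_size + 2 = {subset_size + 2} rows, got {n}"
        )
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    dof = n - subset_size - 1
    if dof < 5:
        warnings.warn(
            f"only {dof} residual degrees of freedom for a {subset_size}-term "
            f"model on {n} molecules; adjusted R^2 near 1 is expected from "
            "overfitting alone",
            DegreesOfFreedomWarning,
            stacklevel=2,
        )
    names = sorted(descriptors.columns)
    best = None
    for combo in itertools.combinations(names, subset_size):
        X = descriptors.loc[:, list(combo)].to_numpy(float)
        fit = _ols(X, y)
        if fit is None:
            warnings.warn(f"collinear descriptor subset skipped: {combo}")
            continue
        coef, r2, resid = fit
        adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
        if best is None or adj > best[0] + 1e-12:
            best = (adj, combo, coef, r2, resid)
    if best is None:
        raise ValueError("no non-collinear descriptor subset found")
    adj, combo, coef, r2, resid = best
    return QsarModel(
        intercept=float(coef[0]),
        terms=tuple((name, float(c)) for name, c in zip(combo, coef[1:])),
        fit_stats={
            "r2": float(r2),
            "adjusted_r2": float(adj),
            "residuals": resid.tolist(),
            "n": n,
            "residual_dof": dof,
        },
    )


def loo_q2(descriptors: pd.DataFrame, response) -> float:
    """Leave-one-out Q^2 = 1 - PRESS/TSS for the given descriptor set.

    Each fold refits the OLS model without one molecule and predicts it;
    TSS is about the full-sample response mean. Folds whose design becomes
    singular are reported and Q^2 is returned as NaN (flagged undefined).
    """
    X = descriptors.to_numpy(float)
    y = np.asarray(response, float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for LOO on {p} descriptors")
    press = 0.0
    bad_folds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = _ols(X[mask], y[mask])
        if fit is None:
            bad_folds.append(i)
            continue
        coef = fit[0]
        pred = coef[0] + X[i] @ coef[1:]
        press += (y[i] - pred) ** 2
    if bad_folds:
        warnings.warn(f"singular LOO folds (left-out rows {bad_folds}); Q^2 undefined")
        return float("nan")
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss
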