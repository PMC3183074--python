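"""Time-resolved lifespan prediction: ridge regression with GCV.

How early does each biomarker become informative?  For each age ``n`` the raw
timecourse values from the first measured day up to ``n``, plus all their
pairwise products ("interaction terms", so rates of change can enter a linear
model), are regressed against lifespan with ridge regression.  The penalty is
chosen automatically as the minimizer of the generalized cross-validation
score ``GCV(lambda) = n * SS_res(lambda) / (n - tr(H(lambda)))^2`` over a log
grid, which keeps the growing feature count from inflating R-squared through
overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import BiomarkerTimecourse

__all__ = ["RidgeGcvModel", "PredictiveCurve", "expand_features",
           "ridge_gcv", "predictive_curve", "DEFAULT_LAMBDA_GRID"]

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 50)


def expand_features(values: np.ndarray) -> np.ndarray:
    """Raw values plus all unordered pairwise products (squares included).

    For d values the feature count is ``d + d (d + 1) / 2``; the ordering is
    deterministic: raw values first, then products (i, j) with i <= j in
    lexicographic order.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    d = v.shape[1]
    feats = [v]
    for i in range(d):
        for j in range(i, d):
            feats.append((v[:, i] * v[:, j])[:, None])
    out = np.hstack(feats)
    return out[0] if np.asarray(values).ndim == 1 else out


@dataclass
class RidgeGcvModel:
    """Standardized ridge fit at the GCV-minimizing penalty."""

    coefficients: np.ndarray     # on standardized predictors
    intercept: float             # on the original y scale
    lambda_: float
    gcv_score: float
    gcv_path: np.ndarray         # GCV per grid point
    lambda_grid: np.ndarray
    r2: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    n: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.feature_means) / self.feature_sds
        return self.intercept + Z @ self.coefficients


def _ridge_path(Z: np.ndarray, y: np.ndarray, lambdas: np.ndarray):
    """Coefficients, residual SS and hat-trace per penalty via one SVD.

    Predictors are already standardized and y centered; the intercept is
    unpenalized (absorbed by centering).
    """
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    Uty = U.T @ y
    n = y.size
    out = []
    for lam in lambdas:
        shrink = s / (s ** 2 + lam)
        beta = Vt.T @ (shrink * Uty)
        fitted = U @ ((s * shrink) * Uty)
        ss_res = float(np.sum((y - fitted) ** 2))
        tr_h = float(np.sum(s ** 2 / (s ** 2 + lam))) + 1.0  # +1: intercept
        out.append((beta, ss_res, tr_h))
    return out


def ridge_gcv(features: np.ndarray, lifespans: np.ndarray,
              lambda_grid: Optional[np.ndarray] = None) -> RidgeGcvModel:
    """Ridge regression with the penalty minimizing GCV over a log grid.

    Predictors are standardized before penalization (constant columns are
    dropped internally); the intercept is unpenalized.  The reported
    R-squared is in-sample at the chosen penalty.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(lifespans, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else \
        np.asarray(lambda_grid, dtype=float)

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    ybar = y.mean()
    yc = y - ybar

    path = _ridge_path(Z, yc, grid)
    gcv = np.array([n * ss / (n - tr) ** 2 for _, ss, tr in path])
    best = int(np.argmin(gcv))
    beta_kept, ss_res, _ = path[best]
    beta = np.zeros(X.shape[1])
    beta[keep] = beta_kept
    ss_tot = float(np.sum(yc ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    sds = np.where(keep, sd, 1.0)
    return RidgeGcvModel(coefficients=beta, intercept=float(ybar),
                         lambda_=float(grid[best]), gcv_score=float(gcv[best]),
                         gcv_path=gcv, lambda_grid=grid, r2=r2,
                         feature_means=mu, feature_sds=sds, n=n)


@dataclass
class PredictiveCurve:
    """Per-age lifespan-predictive R-squared with feature counts."""

    biomarker: str
    ages: List[float]
    r2: List[float]
    n_features: List[int]
    lambdas: List[float]
    n_animals: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "r2": self.r2,
                             "n_features": self.n_features,
                             "lambda": self.lambdas})


def predictive_curve(courses: Sequence[BiomarkerTimecourse],
                     lifespans: Dict[str, float],
                     ages: Sequence[float] = tuple(range(2, 8)),
                     lambda_grid: Optional[np.ndarray] = None,
                     ) -> PredictiveCurve:
    """Lifespan-predictive R-squared as a function of age for one biomarker.

    At each requested age the raw values from the biomarker's first measured
    day up to that age (animals missing any of those days are dropped, their
    count reflected in ``n_animals``) are feature-expanded and fitted by
    :func:`ridge_gcv`.
    """
    if not courses:
        raise ValueError("no timecourses given")
    biomarker = courses[0].biomarker
    by_animal = {}
    for c in courses:
        if c.biomarker != biomarker:
            raise ValueError("curve expects a single biomarker")
        by_animal[c.animal_id] = c
    first_day = max(min(np.min(c.ages) for c in courses), min(ages) - 5)

    out_ages, out_r2, out_nf, out_lam = [], [], [], []
    n_used = 0
    for age in ages:
        day_grid = [d for d in np.arange(np.ceil(first_day), age + 0.5)
                    if d >= first_day]
        if not day_grid:
            continue
        rows, ys = [], []
        for aid, c in by_animal.items():
            if aid not in lifespans:
                continue
            vals = []
            ok = True
            for d in day_grid:
                hit = np.flatnonzero(np.isclose(c.ages, d))
                if hit.size == 0:
                    ok = False
                    break
                vals.append(c.values[hit[0]])
            if ok:
                rows.append(vals)
                ys.append(lifespans[aid])
        if len(rows) < 10:
            raise ValueError(
                f"fewer than 10 animals observed at all days up to {age}")
        X = expand_features(np.asarray(rows))
        model = ridge_gcv(X, np.asarray(ys), lambda_grid)
        out_ages.append(float(age))
        out_r2.append(model.r2)
        out_nf.append(X.shape[1])
        out_lam.append(model.lambda_)
        n_used = len(rows)
    return PredictiveCurve(biomarker=biomarker, ages=out_ages, r2=out_r2,
                           n_features=out_nf, lambdas=out_lam,
                           n_animals=n_used)
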