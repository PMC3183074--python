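"""Tabular statistics for lifespan prediction from early-adulthood biomarkers.

The analysis contract throughout: each biomarker timecourse is summarized in a
closed day window (default days 3-7) by its mean level and the slope of an
ordinary least-squares line; lifespan is regressed on these summaries with
standardized coefficients; significance comes from the F statistic
``F = R^2 * df_err / ((1 - R^2) * df_model)`` with ``df_model = p`` and
``df_err = n - p - 1``; out-of-sample ability is the leave-one-out R-squared,
computed from held-out residuals.  Predicted lifespans can be dichotomized
about the mean into a diagnostic test for above-average longevity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import BiomarkerTimecourse

__all__ = [
    "WindowSummary", "RegressionResult", "DiagnosticTest", "LifespanEstimate",
    "estimate_lifespan", "window_summary", "summary_table", "ols_predict",
    "loo_r2", "survival_prediction_index", "dichotomize_test", "lifespan_kde",
    "ks_compare", "partial_r2_table", "f_from_r2",
]

SURVIVAL_INDEX_PREDICTORS = (
    "length_mean", "length_slope", "motion_mean", "motion_slope",
    "texture_mean", "texture_slope", "autofluorescence_slope",
)


class LifespanEstimate(NamedTuple):
    lifespan_days: Optional[float]
    censored: bool


def estimate_lifespan(observation_ages: Sequence[float],
                      alive: Sequence[bool]) -> LifespanEstimate:
    """Interval-midpoint lifespan estimate.

    Death is localized between the last observation at which the animal
    responded and the first at which it did not; under a uniform prior on the
    time of death within that interval, the expected lifespan is the interval
    midpoint.  An animal never observed dead is right-censored (kept in the
    records, excluded from regressions).
    """
    ages = np.asarray(observation_ages, dtype=float)
    alive = np.asarray(alive, dtype=bool)
    if ages.size == 0 or ages.size != alive.size:
        raise ValueError("observation ages and alive flags must align")
    order = np.argsort(ages)
    ages, alive = ages[order], alive[order]
    dead_idx = np.flatnonzero(~alive)
    if dead_idx.size == 0:
        return LifespanEstimate(None, True)
    first_dead = dead_idx[0]
    if first_dead == 0:
        raise ValueError("animal dead at first observation: no bracket")
    last_alive = ages[first_dead - 1]
    if not alive[first_dead - 1]:
        raise ValueError("no alive observation precedes the first death")
    return LifespanEstimate(0.5 * (last_alive + ages[first_dead]), False)


@dataclass
class WindowSummary:
    biomarker: str
    window: Tuple[float, float]
    mean: float
    slope: Optional[float]
    n_points: int


def window_summary(timecourse: BiomarkerTimecourse,
                   window: Tuple[float, float] = (3.0, 7.0)) -> WindowSummary:
    """Mean level and least-squares slope of a timecourse within the window.

    The slope is left undefined (None, not zero) with fewer than two in-window
    points; the mean needs at least one.
    """
    ages, values = timecourse.in_window(window)
    if ages.size == 0:
        raise ValueError(
            f"no observations of {timecourse.biomarker!r} in window {window}")
    mean = float(np.mean(values))
    slope = None
    if ages.size >= 2 and np.ptp(ages) > 0:
        slope = float(np.polyfit(ages, values, 1)[0])
    return WindowSummary(timecourse.biomarker, tuple(window), mean, slope,
                         int(ages.size))


def summary_table(animals, courses, window=(3.0, 7.0)) -> pd.DataFrame:
    """Per-animal summary DataFrame: lifespan + <biomarker>_mean / _slope.

    Excluded and right-censored animals are dropped (their counts are
    available from the records themselves).
    """
    lifespan = {a.animal_id: a.lifespan_days for a in animals
                if not a.excluded and not a.censored
                and a.lifespan_days is not None}
    rows: Dict[str, Dict[str, float]] = {}
    for c in courses:
        if c.animal_id not in lifespan:
            continue
        ws = window_summary(c, window)
        row = rows.setdefault(c.animal_id, {})
        row[f"{c.biomarker}_mean"] = ws.mean
        if ws.slope is not None:
            row[f"{c.biomarker}_slope"] = ws.slope
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.insert(0, "lifespan_days", pd.Series(lifespan))
    df.index.name = "animal_id"
    return df.dropna()


@dataclass
class RegressionResult:
    predictors: List[str]
    coefficients: np.ndarray       # standardized (beta) weights
    intercept: float
    r2: float
    f_statistic: float
    p_value: float
    df_model: int
    df_error: int
    loo_r2: Optional[float] = None
    predictions: Optional[np.ndarray] = None  # lifespan units
    n: int = 0
    n_dropped: int = 0

    def weights_by_magnitude(self) -> List[Tuple[str, float]]:
        order = np.argsort(-np.abs(self.coefficients))
        return [(self.predictors[i], float(self.coefficients[i]))
                for i in order]


def f_from_r2(r2: float, df_model: int, df_error: int) -> float:
    """F statistic from R-squared: ``R^2 df_err / ((1 - R^2) df_model)``."""
    if r2 >= 1.0:
        return np.inf
    return r2 * df_error / ((1.0 - r2) * df_model)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    return (X - mu) / sd, mu, sd


def _design(features, lifespans):
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(lifespans, dtype=float)
    keep = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    return names, X[keep], y[keep], int((~keep).sum())


def ols_predict(features, lifespans) -> RegressionResult:
    """OLS of lifespan on biomarker summaries with standardized weights.

    Coefficients are reported with both predictors and response expressed in
    SD units ("beta weights"), so their magnitudes are directly comparable;
    R-squared, F and p are invariant to that scaling.  Predictions are
    returned in lifespan units.
    """
    names, X, y, n_dropped = _design(features, lifespans)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    Z, mu, sd = _standardize(X)
    cond = np.linalg.cond(np.column_stack([np.ones(n), Z]))
    if cond > 1e8:
        corr = np.corrcoef(Z, rowvar=False)
        offenders = [
            f"{names[i]}~{names[j]}"
            for i in range(p) for j in range(i + 1, p)
            if p > 1 and abs(np.atleast_2d(corr)[i, j]) > 0.9999]
        raise ValueError(
            f"collinear predictors (cond={cond:.3g}): {offenders or names}")
    ybar, ysd = y.mean(), y.std(ddof=1)
    zy = (y - ybar) / ysd
    A = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(A, zy, rcond=None)
    fitted_z = A @ beta
    resid = zy - fitted_z
    ss_tot = float(np.sum(zy ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    df_model, df_error = p, n - p - 1
    F = f_from_r2(r2, df_model, df_error)
    pval = float(sps.f.sf(F, df_model, df_error))
    return RegressionResult(
        predictors=names, coefficients=beta[1:], intercept=float(beta[0]),
        r2=r2, f_statistic=F, p_value=pval, df_model=df_model,
        df_error=df_error, predictions=ybar + ysd * fitted_z, n=n,
        n_dropped=n_dropped)


def loo_r2(features, lifespans) -> float:
    """Leave-one-out R-squared from held-out residuals.

    Computed with the exact hat-matrix shortcut ``e_i / (1 - h_ii)`` for OLS,
    which reproduces the naive n-refit procedure to machine precision.
    """
    names, X, y, _ = _design(features, lifespans)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    # h_ii via the economy QR of the design
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q ** 2, axis=1)
    e_loo = resid / (1.0 - h)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(e_loo ** 2)) / ss_tot


def survival_prediction_index(summaries: pd.DataFrame,
                              lifespans=None) -> RegressionResult:
    """The seven-predictor multivariate longevity model.

    Predictors: length (mean, slope), motion (mean, slope), texture (mean,
    slope) and autofluorescence (slope), all as day-window summaries.  Weights
    are standardized and reported in descending magnitude via
    :meth:`RegressionResult.weights_by_magnitude`.
    """
    if lifespans is None:
        lifespans = summaries["lifespan_days"]
    missing = [c for c in SURVIVAL_INDEX_PREDICTORS
               if c not in summaries.columns]
    if missing:
        raise ValueError(f"missing survival-index predictors: {missing}")
    X = summaries[list(SURVIVAL_INDEX_PREDICTORS)]
    res = ols_predict(X, lifespans)
    res.loo_r2 = loo_r2(X, lifespans)
    return res


@dataclass
class DiagnosticTest:
    sensitivity: float
    specificity: float
    mean_lifespan_ratio: float
    ks_statistic: float
    ks_p: float
    threshold_rule: str = "above/below mean"


def dichotomize_test(predictions, lifespans) -> DiagnosticTest:
    """Above/below-average predicted longevity as a diagnostic test.

    Sensitivity = P(predicted above average | actually above average);
    specificity the converse.  Also reports the ratio of mean lifespans
    between the predicted-long and predicted-short cohorts, and a two-tailed
    KS comparison of their lifespan distributions.
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(lifespans, dtype=float)
    pred_above = pred > pred.mean()
    actual_above = y > y.mean()
    if min(pred_above.sum(), (~pred_above).sum()) < 2 or \
            min(actual_above.sum(), (~actual_above).sum()) < 2:
        raise ValueError("degenerate split about the mean")
    sens = float(np.mean(pred_above[actual_above]))
    spec = float(np.mean(~pred_above[~actual_above]))
    ratio = float(y[pred_above].mean() / y[~pred_above].mean())
    ks, p = ks_compare(y[pred_above], y[~pred_above])
    return DiagnosticTest(sens, spec, ratio, ks, p)


class LifespanKde:
    """Gaussian KDE with kernel variance ``sigma^2 * n^-0.2``.

    Note this is the rule as printed for this analysis (variance, not SD,
    scaled by n^-0.2); it is deliberately wider than the textbook univariate
    Scott factor.
    """

    def __init__(self, data):
        data = np.asarray(data, dtype=float)
        if data.size < 2:
            raise ValueError("need at least two observations")
        var = data.var(ddof=1)
        if var == 0:
            raise ValueError("zero variance")
        self.n = data.size
        self.kernel_variance = var * self.n ** -0.2
        # gaussian_kde's bw factor multiplies the data SD, so a factor of
        # n^-0.1 yields kernel variance var * n^-0.2 exactly.
        self._kde = sps.gaussian_kde(data, bw_method=self.n ** -0.1)
        self.data = data

    def __call__(self, grid):
        return self._kde(np.asarray(grid, dtype=float))

    def grid(self, n_points: int = 512, pad_sd: float = 4.0):
        sd = self.data.std(ddof=1)
        return np.linspace(self.data.min() - pad_sd * sd,
                           self.data.max() + pad_sd * sd, n_points)


def lifespan_kde(lifespans) -> LifespanKde:
    return LifespanKde(lifespans)


def ks_compare(a, b) -> Tuple[float, float]:
    """Two-sample two-tailed Kolmogorov-Smirnov test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(v.size), C]) if C.size else \
        np.ones((v.size, 1))
    beta, *_ = np.linalg.lstsq(A, v, rcond=None)
    return v - A @ beta


def partial_r2_table(summaries: pd.DataFrame, lifespans,
                     biomarkers: Sequence[str],
                     controls: Dict[str, Sequence[str]]) -> pd.DataFrame:
    """R-squared with lifespan after controlling for other markers.

    For each biomarker column and each named control set, both the biomarker
    and lifespan are residualized on the controls by OLS; the squared
    correlation of the residuals is reported as a percentage of the
    uncontrolled R-squared.
    """
    y = np.asarray(lifespans, dtype=float)
    out = {}
    for b in biomarkers:
        v = summaries[b].to_numpy(dtype=float)
        base = ols_predict(v[:, None], y).r2
        row = {"r2": base}
        for cname, cset in controls.items():
            cset = [c for c in cset]
            C = summaries[cset].to_numpy(dtype=float) if cset else \
                np.empty((y.size, 0))
            rv = _residualize(v, C)
            ry = _residualize(y, C)
            if np.allclose(rv, 0, atol=1e-10 * max(1.0, np.abs(v).max())):
                row[cname] = 0.0
            else:
                r = np.corrcoef(rv, ry)[0, 1]
                row[cname] = 100.0 * (r * r) / base
        out[b] = row
    return pd.DataFrame.from_dict(out, orient="index")
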