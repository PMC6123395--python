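"""Trait–SOC regression models and the LOI→C calibration.

Three functional forms cover the survey's trait–SOC relationships:

* linear: ``y = a·x + b``
* logarithmic: ``y = a·ln(x) + b``
* exponential: ``y = a·e^(b·x)``

Linear and logarithmic fits are closed-form ordinary least squares;
the exponential is true nonlinear least squares on the original scale,
initialised from the log-linearised fit (additive noise on y breaks
log-space optimality, so log-linearisation alone is not enough).
Goodness of fit is R² on the original scale; model selection uses
small-sample AICc by default, with ties broken toward the simpler
form (linear over log over exponential).

Total soil C correlates strongly with loss on ignition (LOI); for
calcareous soils, whose combustion signal is confounded by inorganic
carbonate, total C is predicted from the LOI–C line fitted on the
non-calcareous records (:func:`loi_carbon_calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FORMS",
    "ModelFit",
    "CalibrationResult",
    "FunctionalFormRegressor",
    "LOICarbonCalibrator",
    "fit_model",
    "select_model",
    "loi_carbon_calibration",
]

FORMS = ("linear", "log", "exponential")

# parameters counted by AICc: a, b and the residual variance
_K = 3


@dataclass(frozen=True)
class ModelFit:
    """A fitted two-parameter trait–SOC model."""

    form: str
    a: float
    b: float
    r_squared: float
    aicc: float
    n: int
    notes: tuple = ()

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.a * x + self.b
        if self.form == "log":
            return self.a * np.log(x) + self.b
        return self.a * np.exp(self.b * x)


def _aicc(sse: float, n: int) -> float:
    if n - _K - 1 <= 0:
        return float("inf")
    sse = max(sse, 1e-300)
    aic = n * np.log(sse / n) + 2 * _K
    return float(aic + 2 * _K * (_K + 1) / (n - _K - 1))


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    if sst <= 0:
        return 0.0
    return 1.0 - sse / sst


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form slope/intercept of y on x."""
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("degenerate fit: predictor is constant")
    a = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    return a, float(y.mean() - a * x.mean())


def fit_model(x, y, form: str) -> ModelFit:
    """Fit one functional form to (x, y) by least squares.

    The exponential form requires ``y > 0`` (for the log-linearised
    initial guess) and the log form ``x > 0``. R² is computed on the
    original y scale. Raises ``ValueError`` for a constant predictor or
    an inadmissible form.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form '{form}'; expected one of {FORMS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")

    if form == "linear":
        a, b = _ols(x, y)
    elif form == "log":
        if np.any(x <= 0):
            raise ValueError("log form requires x > 0")
        a, b = _ols(np.log(x), y)
    else:
        if np.any(y <= 0):
            raise ValueError("exponential form requires y > 0 for initialization")
        # initial guess from the log-linearised model ln y = ln a + b x
        slope, intercept = _ols(x, np.log(y))
        a0, b0 = float(np.exp(intercept)), slope
        try:
            (a, b), _ = curve_fit(
                lambda t, aa, bb: aa * np.exp(bb * t), x, y, p0=(a0, b0), maxfev=10000
            )
        except RuntimeError:
            a, b = a0, b0
        a, b = float(a), float(b)

    fit = ModelFit(form, a, b, 0.0, 0.0, n)
    pred = fit.predict(x)
    sse = float(np.sum((y - pred) ** 2))
    return ModelFit(form, a, b, _r2(y, pred), _aicc(sse, n), n)


def select_model(
    x,
    y,
    forms=FORMS,
    *,
    criterion: str = "aicc",
    tol: float = 1e-8,
) -> ModelFit:
    """Fit every admissible form and return the best by the criterion.

    ``criterion`` is ``"aicc"`` (lower wins, default) or ``"r2"``
    (higher wins). Near-ties (within ``tol``) go to the simpler form in
    the order linear, log, exponential. Inadmissible forms (e.g. log
    with zero x) are listed in the winning fit's ``notes``.
    """
    if criterion not in ("aicc", "r2"):
        raise ValueError("criterion must be 'aicc' or 'r2'")
    fits: list[ModelFit] = []
    excluded: list[str] = []
    for form in forms:
        try:
            fits.append(fit_model(x, y, form))
        except (ValueError, RuntimeError) as exc:
            excluded.append(f"{form}: {exc}")
    if not fits:
        raise ValueError("no admissible form; " + "; ".join(excluded))

    def score(f: ModelFit) -> float:
        return f.aicc if criterion == "aicc" else -f.r_squared

    # simpler-first order so ties resolve to the simpler form
    order = {f: i for i, f in enumerate(FORMS)}
    fits.sort(key=lambda f: order[f.form])
    best = fits[0]
    for f in fits[1:]:
        if score(f) < score(best) - tol:
            best = f
    return ModelFit(
        best.form, best.a, best.b, best.r_squared, best.aicc, best.n,
        notes=tuple(f"excluded {e}" for e in excluded),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """LOI→C calibration line with predictions for calcareous records."""

    slope: float
    intercept: float
    r_squared: float
    n_calibration: int
    predicted_c: pd.Series = field(repr=False)

    def predict(self, loi):
        return self.slope * np.asarray(loi, dtype=float) + self.intercept


def loi_carbon_calibration(loi, c, calcareous) -> CalibrationResult:
    """Calibrate total C on LOI and predict C for calcareous records.

    The line is ordinary least squares of C on LOI over the
    non-calcareous records only; ``predicted_c`` holds predictions
    indexed by the positions of the calcareous records (empty when
    there are none). Requires at least 3 non-calcareous records.
    """
    loi = np.asarray(loi, dtype=float)
    c = np.asarray(c, dtype=float)
    calc = np.asarray(calcareous, dtype=bool)
    if not (loi.shape == c.shape == calc.shape):
        raise ValueError("loi, c and calcareous must have identical shapes")
    ref = ~calc
    if ref.sum() < 3:
        raise ValueError("insufficient data: need >= 3 non-calcareous records")
    slope, intercept = _ols(loi[ref], c[ref])
    pred_ref = slope * loi[ref] + intercept
    r2 = _r2(c[ref], pred_ref)
    idx = np.nonzero(calc)[0]
    predicted = pd.Series(slope * loi[idx] + intercept, index=idx, name="predicted_c")
    return CalibrationResult(slope, intercept, r2, int(ref.sum()), predicted)


class FunctionalFormRegressor(RegressorMixin, BaseEstimator):
    """sklearn-style regressor over one functional form (or auto-select).

    Parameters
    ----------
    form :
        ``"linear"``, ``"log"``, ``"exponential"`` or ``"auto"`` (select
        by ``criterion`` across all admissible forms).
    criterion :
        Selection criterion when ``form="auto"``.

    Attributes
    ----------
    form_, a_, b_, r_squared_, aicc_, n_ : the fitted model.
    """

    def __init__(self, form: str = "auto", criterion: str = "aicc"):
        self.form = form
        self.criterion = criterion

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single predictor column")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        x = self._as_1d(X)
        y = np.asarray(y, dtype=float)
        if self.form == "auto":
            fit = select_model(x, y, criterion=self.criterion)
        else:
            fit = fit_model(x, y, self.form)
        self.fit_ = fit
        self.form_ = fit.form
        self.a_, self.b_ = fit.a, fit.b
        self.r_squared_, self.aicc_, self.n_ = fit.r_squared, fit.aicc, fit.n
        return self

    def predict(self, X):
        return self.fit_.predict(self._as_1d(X))


class LOICarbonCalibrator(RegressorMixin, BaseEstimator):
    """sklearn-style wrapper for :func:`loi_carbon_calibration`.

    ``fit(X, y, calcareous=...)`` takes LOI (%) as the single predictor
    and total C (%) as the response; calcareous records are excluded
    from the calibration and ``predict`` serves their C estimates.
    """

    def fit(self, X, y, calcareous=None):
        loi = FunctionalFormRegressor._as_1d(X)
        if calcareous is None:
            calcareous = np.zeros(loi.shape, dtype=bool)
        result = loi_carbon_calibration(loi, y, calcareous)
        self.slope_ = result.slope
        self.intercept_ = result.intercept
        self.r_squared_ = result.r_squared
        self.n_calibration_ = result.n_calibration
        return self

    def predict(self, X):
        return self.slope_ * FunctionalFormRegressor._as_1d(X) + self.intercept_


def segment_model_table(
    traits: pd.DataFrame,
    threshold: float,
    *,
    trait_names=("cue", "turnover", "qco2", "enzyme_investment"),
    x_col: str = "c_pct",
    criterion: str = "aicc",
) -> pd.DataFrame:
    """Fit each trait against SOC per pH segment and pooled.

    Rows with a NaN trait value are dropped per trait. Returns a tidy
    summary (segment, trait, form, a, b, r_squared, aicc, n); segments
    are ``below`` (pH ≤ threshold), ``above`` and ``all``.
    """
    from soilcue.partitioning import segregate

    below, above = segregate(traits, threshold)
    rows = []
    for segment, part in (("below", below), ("above", above), ("all", traits)):
        for trait in trait_names:
            sub = part[[x_col, trait]].dropna()
            if len(sub) < 3:
                continue
            try:
                fit = select_model(
                    sub[x_col].to_numpy(), sub[trait].to_numpy(), criterion=criterion
                )
            except ValueError:
                continue
            rows.append(
                {
                    "segment": segment,
                    "trait": trait,
                    "form": fit.form,
                    "a": fit.a,
                    "b": fit.b,
                    "r_squared": fit.r_squared,
                    "aicc": fit.aicc,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
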