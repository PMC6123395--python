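"""Edaphic partitioning: regression-tree split search and pH threshold.

Two complementary procedures identify how soil properties partition the
trait–SOC relationships:

* :class:`SingleSplitTree` performs the first (and only) split of a
  regression tree — an exhaustive search over candidate edaphic
  variables (pH, moisture, clay, C, N, C:N) and every midpoint between
  consecutive sorted unique values, choosing the split that minimises
  the pooled within-node sum of squared errors of the response trait.
  The study uses this solely to pick the best single partitioning
  variable, so no recursion, pruning or surrogate splits are
  implemented.

* :class:`SlopeFailureDetector` locates the pH threshold by a
  slope-failure (piecewise-regression) test: a window of fixed width
  (default 1.4 pH units) slides over the pH axis in 0.1-unit steps;
  within each window the response (CUE) is regressed on SOC and the
  window R² recorded. Scanning from high to low pH, the threshold is
  the last window anchor before the R² drops dramatically —
  operationalised as falling below ``drop_fraction`` (default 0.5) of
  the maximum window R². A threshold is only reported as *detected*
  when at least one window's R² exceeds a null quantile (Šidák-adjusted
  across windows) of the no-association R² distribution, so pure-noise
  profiles come back undetected.

Records with pH exactly equal to a threshold belong to the
below-or-equal side throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PartitionCandidate",
    "ThresholdConfig",
    "ThresholdResult",
    "SingleSplitTree",
    "SlopeFailureDetector",
    "best_partition_split",
    "slope_failure_threshold",
    "segregate",
]

DEFAULT_CANDIDATES = ["ph", "moisture_pct", "clay_pct", "c_pct", "n_pct", "cn_ratio"]


@dataclass(frozen=True)
class PartitionCandidate:
    """Best single-split choice: variable, split point, SSE reduction."""

    variable_name: str
    split_value: float
    sse_reduction: float
    uninformative: bool = False


@dataclass(frozen=True)
class ThresholdConfig:
    """Sliding-window slope-failure test configuration.

    ``window_width`` and ``step`` are in pH units; a window anchored at
    grid value ``t`` covers ``[t, t + window_width)``. ``drop_fraction``
    operationalises "R² dropped dramatically": a window fails when its
    R² falls below ``drop_fraction`` times the maximum window R².
    ``detection_alpha`` is the familywise false-detection rate of the
    null (no-association) test.
    """

    window_width: float = 1.4
    step: float = 0.1
    min_points_per_window: int = 10
    drop_fraction: float = 0.5
    detection_alpha: float = 0.05
    outlier_sd: float = 4.0
    failure_persistence: int = 4

    def validate(self) -> None:
        if not (self.window_width > self.step > 0):
            raise ValueError("require window_width > step > 0")
        if self.min_points_per_window < 3:
            raise ValueError("min_points_per_window must be >= 3")
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must lie in (0, 1)")
        if not (0 < self.detection_alpha < 1):
            raise ValueError("detection_alpha must lie in (0, 1)")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")
        if self.failure_persistence < 1:
            raise ValueError("failure_persistence must be >= 1")


@dataclass
class ThresholdResult:
    """Detected pH threshold with the full window-R² profile.

    ``threshold`` is NaN when no threshold was detected; ``profile`` has
    one row per window anchor with columns ``t``, ``r_squared``, ``n``
    and ``skipped`` (window underpopulated).
    """

    threshold: float
    profile: pd.DataFrame
    detected: bool


# ---------------------------------------------------------------------------
# single-split regression tree


def _node_sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def best_partition_split(
    table: pd.DataFrame,
    response: str,
    candidates: list[str] | None = None,
    *,
    min_leaf: int = 5,
) -> PartitionCandidate:
    """Exhaustive best single split of ``response`` by edaphic variables.

    For every candidate variable and every midpoint between consecutive
    sorted unique values (leaving at least ``min_leaf`` rows per side),
    the pooled within-node SSE of the response is evaluated; the
    (variable, split) with the largest SSE reduction wins. Ties go to
    the earlier candidate in list order and then the smaller split
    value, so the search is deterministic. Candidates with fewer than
    two distinct values are skipped; a constant response yields an
    ``uninformative`` result with zero reduction.
    """
    candidates = DEFAULT_CANDIDATES if candidates is None else candidates
    if response not in table.columns:
        raise KeyError(f"response column '{response}' not in table")
    y_all = table[response].to_numpy(dtype=float)
    if np.any(np.isnan(y_all)):
        raise ValueError("response contains missing values")
    n = y_all.size
    if n < 2 * min_leaf:
        raise ValueError(
            f"insufficient data: {n} rows < 2*min_leaf = {2 * min_leaf}"
        )
    total_sse = _node_sse(y_all)

    best: PartitionCandidate | None = None
    usable = 0
    for var in candidates:
        if var not in table.columns:
            raise KeyError(f"candidate column '{var}' not in table")
        v = table[var].to_numpy(dtype=float)
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], y_all[order]
        uniq = np.unique(vs)
        if uniq.size < 2:
            continue
        usable += 1
        # prefix sums over the sorted order give every split's SSE in O(n)
        cs, cs2 = np.cumsum(ys), np.cumsum(ys**2)
        boundaries = np.nonzero(np.diff(vs) > 0)[0]  # split after index i
        for i in boundaries:
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            sl = cs[i]
            sl2 = cs2[i]
            sse_left = sl2 - sl * sl / nl
            sr = cs[-1] - sl
            sr2 = cs2[-1] - sl2
            sse_right = sr2 - sr * sr / nr
            reduction = total_sse - (sse_left + sse_right)
            split = 0.5 * (vs[i] + vs[i + 1])
            if best is None or reduction > best.sse_reduction:
                best = PartitionCandidate(var, float(split), float(max(reduction, 0.0)))
    if usable == 0:
        raise ValueError("no candidate variable has two distinct values")
    if best is None:
        raise ValueError(
            "no admissible split leaves min_leaf rows on both sides"
        )
    if best.sse_reduction <= 1e-12 * max(total_sse, 1.0):
        best = PartitionCandidate(best.variable_name, best.split_value, 0.0, True)
    return best


class SingleSplitTree(RegressorMixin, BaseEstimator):
    """Depth-1 regression tree over edaphic candidate variables.

    Parameters
    ----------
    candidates :
        Column names searched; defaults to the six edaphic properties.
    min_leaf :
        Minimum rows on each side of the split.

    Attributes
    ----------
    variable_, split_value_, sse_reduction_, uninformative_ :
        The winning split (see :func:`best_partition_split`).
    left_mean_, right_mean_ :
        Node means used by :meth:`predict`.
    """

    def __init__(self, candidates: list[str] | None = None, min_leaf: int = 5):
        self.candidates = candidates
        self.min_leaf = min_leaf

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        table = X.copy()
        table["__response__"] = y
        cand = self.candidates or [c for c in DEFAULT_CANDIDATES if c in X.columns]
        result = best_partition_split(
            table, "__response__", cand, min_leaf=self.min_leaf
        )
        self.variable_ = result.variable_name
        self.split_value_ = result.split_value
        self.sse_reduction_ = result.sse_reduction
        self.uninformative_ = result.uninformative
        mask = X[self.variable_].to_numpy(dtype=float) <= self.split_value_
        self.left_mean_ = float(y[mask].mean())
        self.right_mean_ = float(y[~mask].mean())
        return self

    def predict(self, X: pd.DataFrame):
        v = X[self.variable_].to_numpy(dtype=float)
        return np.where(v <= self.split_value_, self.left_mean_, self.right_mean_)


# ---------------------------------------------------------------------------
# slope-failure threshold


def _window_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R² of the simple regression y ~ x; 0 for degenerate windows."""
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if sxx <= 0 or syy <= 0:
        return 0.0
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    return float(sxy * sxy / (sxx * syy))


def _null_r2_quantile(n: int, alpha_each: float) -> float:
    """Upper quantile of R² under no association for an n-point window.

    For simple linear regression on n exchangeable points the null R²
    follows Beta(1/2, (n-2)/2).
    """
    if n < 4:
        return 1.0
    return float(stats.beta.ppf(1.0 - alpha_each, 0.5, (n - 2) / 2.0))


def slope_failure_threshold(
    ph,
    x,
    y,
    config: ThresholdConfig | None = None,
) -> ThresholdResult:
    """Locate the pH threshold where the y ~ x regression collapses.

    Windows ``[t, t + window_width)`` are anchored on the absolute
    ``step`` grid covering the observed pH range. Within each window
    with at least ``min_points_per_window`` records, y (CUE) is
    regressed on x (SOC) and the R² recorded.

    The threshold is the last pH value before the relationship fails,
    located by a descending piecewise scan. Starting from the leading
    run of windows whose R² stays at or above
    ``drop_fraction × max(R²)``, the intact regression is extended
    downward one grid step at a time; the scan stops when either (a)
    a record entering the regression is a gross outlier to the intact
    fit (absolute standardised residual above ``outlier_sd`` — the
    slope-failure signature of crossing into the other regime), or (b)
    the window's R² falls below the drop cutoff. The reported
    threshold is the lowest observed pH among the records accepted as
    intact, snapped down to the step grid, because the break must lie
    below every record that follows the intact regression. If no
    window ever fails, the profile is flat and the threshold is the
    smallest valid anchor.

    ``detected`` is False when no window R² clears the Šidák-adjusted
    null quantile, in which case the threshold is NaN.
    """
    config = config or ThresholdConfig()
    config.validate()
    ph = np.asarray(ph, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (ph.shape == x.shape == y.shape):
        raise ValueError("ph, x and y must have identical shapes")
    if ph.size < config.min_points_per_window:
        raise ValueError("fewer records than min_points_per_window")

    step = config.step
    i0 = int(np.floor(ph.min() / step + 1e-9))
    i1 = int(np.ceil((ph.max() - config.window_width) / step - 1e-9))
    i1 = max(i1, i0)
    anchors = np.round(np.arange(i0, i1 + 1) * step, 10)

    rows = []
    for t in anchors:
        mask = (ph >= t) & (ph < t + config.window_width)
        nwin = int(mask.sum())
        skipped = nwin < config.min_points_per_window
        r2 = np.nan if skipped else _window_r2(x[mask], y[mask])
        rows.append({"t": t, "r_squared": r2, "n": nwin, "skipped": skipped})
    profile = pd.DataFrame(rows)

    valid = profile[~profile["skipped"]]
    if valid.empty:
        raise ValueError("all windows underpopulated; widen the window")

    # null calibration: familywise alpha over the valid windows
    m = len(valid)
    alpha_each = 1.0 - (1.0 - config.detection_alpha) ** (1.0 / m)
    exceeds = [
        r2 > _null_r2_quantile(nwin, alpha_each)
        for r2, nwin in zip(valid["r_squared"], valid["n"])
    ]
    detected = bool(np.any(exceeds))
    if not detected:
        return ThresholdResult(float("nan"), profile, False)

    cutoff = config.drop_fraction * float(valid["r_squared"].max())
    ts = valid["t"].to_numpy(dtype=float)
    r2s = valid["r_squared"].to_numpy(dtype=float)
    if np.all(r2s >= cutoff) or len(valid) < 2:
        # flat profile: no slope failure anywhere in range
        return ThresholdResult(float(ts.min()), profile, True)

    # start the descending scan at the top of the leading run of
    # passing windows (leading failures in the sparse top are skipped)
    top = len(ts) - 1
    while top >= 0 and r2s[top] < cutoff:
        top -= 1
    t0 = ts[top]

    def _fit(mask: np.ndarray):
        xs, ys = x[mask], y[mask]
        sxx = np.sum((xs - xs.mean()) ** 2)
        slope = np.sum((xs - xs.mean()) * (ys - ys.mean())) / sxx if sxx > 0 else 0.0
        intercept = ys.mean() - slope * xs.mean()
        resid = ys - (slope * xs + intercept)
        dof = max(mask.sum() - 2, 1)
        return slope, intercept, float(np.sqrt(np.sum(resid**2) / dof))

    # extend the intact regression downward one grid step at a time
    intact = ph >= t0
    slope, intercept, sigma = _fit(intact)
    for i in range(top - 1, -1, -1):
        t = ts[i]
        new = (ph >= t) & (ph < t + step) & ~intact
        if new.any() and sigma > 0:
            resid = y[new] - (slope * x[new] + intercept)
            if np.any(np.abs(resid) > config.outlier_sd * sigma):
                break  # regime break: entering records reject the fit
        if r2s[i] < cutoff and np.all(r2s[max(i - config.failure_persistence + 1, 0): i + 1] < cutoff):
            break  # dramatic, persistent R² drop
        intact |= new
        slope, intercept, sigma = _fit(intact)

    # the break lies below every record that follows the intact
    # regression; snap the lowest intact pH down to the grid
    lowest = float(ph[intact].min())
    threshold = float(np.round(np.floor(lowest / step + 1e-9) * step, 10))
    return ThresholdResult(threshold, profile, True)


class SlopeFailureDetector(BaseEstimator):
    """Estimator wrapper for :func:`slope_failure_threshold`.

    ``fit(X, y)`` takes ``X`` as a two-column array or DataFrame
    ``(ph, soc)`` and ``y`` as the response trait (CUE); fitted
    attributes are ``threshold_``, ``detected_`` and ``profile_``.
    """

    def __init__(
        self,
        window_width: float = 1.4,
        step: float = 0.1,
        min_points_per_window: int = 10,
        drop_fraction: float = 0.5,
        detection_alpha: float = 0.05,
    ):
        self.window_width = window_width
        self.step = step
        self.min_points_per_window = min_points_per_window
        self.drop_fraction = drop_fraction
        self.detection_alpha = detection_alpha

    def _config(self) -> ThresholdConfig:
        return ThresholdConfig(
            window_width=self.window_width,
            step=self.step,
            min_points_per_window=self.min_points_per_window,
            drop_fraction=self.drop_fraction,
            detection_alpha=self.detection_alpha,
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            ph = X.iloc[:, 0].to_numpy(dtype=float)
            soc = X.iloc[:, 1].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            ph, soc = X[:, 0], X[:, 1]
        result = slope_failure_threshold(ph, soc, y, self._config())
        self.threshold_ = result.threshold
        self.detected_ = result.detected
        self.profile_ = result.profile
        return self


def segregate(table: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a table at a pH threshold (``ph == threshold`` goes below).

    Returns ``(below_or_equal, above)``; the two parts are disjoint and
    exhaustive.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = table["ph"].to_numpy(dtype=float) <= threshold
    return table.loc[mask], table.loc[~mask]
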