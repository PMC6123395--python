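"""Regression-tree split search and slope-failure threshold detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from soilcue.partitioning import (
    SingleSplitTree,
    SlopeFailureDetector,
    ThresholdConfig,
    best_partition_split,
    segregate,
    slope_failure_threshold,
)
from soilcue.physiology import derive_traits
from soilcue.synthetic import SurveyConfig, generate_survey


def brute_force_split(table, response, candidates, min_leaf=5):
    """Independent exhaustive reference: every (variable, midpoint) pair."""
    y = table[response].to_numpy(dtype=float)
    total = np.sum((y - y.mean()) ** 2)
    best = None
    for var in candidates:
        v = table[var].to_numpy(dtype=float)
        uniq = np.sort(np.unique(v))
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            split = (lo + hi) / 2.0
            left, right = y[v <= split], y[v > split]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sse = sum((part - part.mean()) @ (part - part.mean()) for part in (left, right))
            red = total - sse
            if best is None or red > best[2]:
                best = (var, split, red)
    return best


class TestBestPartitionSplit:
    def test_recovers_planted_step_in_ph(self, rng):
        n = 60
        ph = rng.uniform(4, 9, n)
        table = pd.DataFrame(
            {
                "ph": ph,
                "moisture_pct": rng.uniform(10, 80, n),
                "clay_pct": rng.uniform(5, 40, n),
                "resp": np.where(ph > 6.0, 1.0, 0.0),
            }
        )
        result = best_partition_split(table, "resp", ["ph", "moisture_pct", "clay_pct"])
        assert result.variable_name == "ph"
        below = ph[ph <= 6.0].max()
        above = ph[ph > 6.0].min()
        assert below < result.split_value < above
        assert not result.uninformative

    def test_constant_response_flagged_uninformative(self, rng):
        table = pd.DataFrame({"ph": rng.uniform(4, 9, 30), "resp": np.ones(30)})
        result = best_partition_split(table, "resp", ["ph"])
        assert result.uninformative and result.sse_reduction == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 50))
        cand = ["a", "b", "c"]
        table = pd.DataFrame({c: rng.normal(size=n) for c in cand})
        table["y"] = rng.normal(size=n)
        got = best_partition_split(table, "y", cand)
        var, split, red = brute_force_split(table, "y", cand)
        assert got.variable_name == var
        assert got.split_value == pytest.approx(split)
        assert got.sse_reduction == pytest.approx(red, rel=1e-9)

    def test_agrees_with_sklearn_depth_one_tree(self, rng):
        n = 80
        table = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)}
        )
        y = rng.normal(size=n) + (table["a"] > 0.3) * 2.0
        tree = DecisionTreeRegressor(max_depth=1, min_samples_leaf=5).fit(table, y)
        got = best_partition_split(table.assign(y=y), "y", ["a", "b"])
        assert got.variable_name == ["a", "b"][tree.tree_.feature[0]]
        assert got.split_value == pytest.approx(tree.tree_.threshold[0], rel=1e-6)

    def test_insufficient_rows_raise(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=6), "y": rng.normal(size=6)})
        with pytest.raises(ValueError, match="insufficient"):
            best_partition_split(table, "y", ["a"])

    def test_estimator_predicts_node_means(self, rng):
        n = 60
        X = pd.DataFrame({"a": rng.normal(size=n)})
        y = np.where(X["a"] > 0, 5.0, 1.0) + rng.normal(0, 0.1, n)
        tree = SingleSplitTree(candidates=["a"]).fit(X, y)
        pred = tree.predict(X)
        assert set(np.round(pred, 1)) == {
            round(tree.left_mean_, 1),
            round(tree.right_mean_, 1),
        }
        assert tree.sse_reduction_ > 0

    def test_survey_partition_variable_is_ph(self, survey_default):
        traits = derive_traits(survey_default)
        table = survey_default[
            ["ph", "moisture_pct", "clay_pct", "c_pct", "n_pct"]
        ].copy()
        table["cn_ratio"] = traits["cn_ratio"]
        table["cue"] = traits["cue"]
        result = best_partition_split(
            table, "cue", ["ph", "moisture_pct", "clay_pct", "c_pct", "n_pct", "cn_ratio"]
        )
        assert result.variable_name == "ph"


class TestSlopeFailureThreshold:
    def test_threshold_on_grid_and_profile_in_range(self, survey_default):
        traits = derive_traits(survey_default)
        result = slope_failure_threshold(
            traits["ph"], traits["c_pct"], traits["cue"]
        )
        prof = result.profile
        valid = prof[~prof["skipped"]]
        assert valid["r_squared"].between(0, 1).all()
        assert result.detected
        assert round(result.threshold * 10) == pytest.approx(result.threshold * 10)

    def test_recovers_planted_break(self):
        hits = 0
        for seed in range(6):
            frame = generate_survey(SurveyConfig(ph_break=6.2, seed=seed))
            traits = derive_traits(frame)
            result = slope_failure_threshold(traits["ph"], traits["c_pct"], traits["cue"])
            hits += result.detected and abs(result.threshold - 6.2) <= 0.1 + 1e-9
        assert hits >= 5

    def test_identity_relation_gives_flat_profile(self, rng):
        ph = rng.uniform(4, 8, 200)
        x = rng.uniform(1, 10, 200)
        result = slope_failure_threshold(ph, x, x.copy())
        valid = result.profile[~result.profile["skipped"]]
        assert (valid["r_squared"] > 0.999).all()
        assert result.threshold == pytest.approx(valid["t"].min())

    def test_pure_noise_is_not_detected(self):
        misses = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ph = rng.uniform(4, 8, 170)
            x = rng.uniform(1, 10, 170)
            y = rng.normal(0.05, 0.01, 170)
            result = slope_failure_threshold(ph, x, y)
            misses += not result.detected
            if not result.detected:
                assert np.isnan(result.threshold)
        assert misses >= 9

    def test_underpopulated_windows_are_skipped_or_error(self, rng):
        ph = np.array([4.0, 4.1, 4.2, 7.9, 8.0, 8.1, 8.2, 8.3, 8.25, 8.05])
        x = rng.uniform(1, 5, 10)
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            slope_failure_threshold(ph, x, y, ThresholdConfig(min_points_per_window=11))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ThresholdConfig(window_width=0.05, step=0.1).validate()
        with pytest.raises(ValueError):
            ThresholdConfig(min_points_per_window=2).validate()
        with pytest.raises(ValueError):
            ThresholdConfig(drop_fraction=1.5).validate()

    def test_estimator_wrapper_matches_function(self, survey_default):
        traits = derive_traits(survey_default)
        det = SlopeFailureDetector().fit(
            traits[["ph", "c_pct"]], traits["cue"].to_numpy()
        )
        direct = slope_failure_threshold(traits["ph"], traits["c_pct"], traits["cue"])
        assert det.threshold_ == direct.threshold
        assert det.detected_ == direct.detected


class TestSegregate:
    def test_boundary_goes_below(self):
        table = pd.DataFrame({"ph": [6.1, 6.2, 6.3]})
        below, above = segregate(table, 6.2)
        assert len(below) == 2 and len(above) == 1

    def test_empty_and_conservation(self, survey_default):
        below, above = segregate(survey_default, 6.2)
        assert len(below) + len(above) == len(survey_default)
        b2, a2 = segregate(survey_default.iloc[0:0], 6.2)
        assert len(b2) == len(a2) == 0

    def test_nonfinite_threshold_rejected(self, survey_default):
        with pytest.raises(ValueError):
            segregate(survey_default, float("nan"))
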