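"""IndVal scores, permutation significance, class roll-ups, rarefaction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilcue.indicators import (
    IndicatorValueAnalysis,
    aggregate_by_class,
    indval_scores,
    indval_significance,
    rarefied_richness,
)
from soilcue.synthetic import FeatureTableConfig, generate_feature_table


def toy_matrix():
    m = pd.DataFrame(
        [[5.0, 5.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0]],
        index=["conc", "grad", "flat"],
        columns=["a1", "a2", "b1", "b2"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=m.columns)
    return m, groups


def oracle_scores(matrix, labels):
    """Hand-rolled spreadsheet-style A x B computation."""
    out = {}
    groups = sorted(set(labels.values()))
    for fid, row in matrix.iterrows():
        means = {g: np.mean([row[s] for s in matrix.columns if labels[s] == g]) for g in groups}
        tot = sum(means.values())
        scores = {}
        for g in groups:
            a = means[g] / tot if tot > 0 else 0.0
            cols = [s for s in matrix.columns if labels[s] == g]
            b = np.mean([row[s] > 0 for s in cols])
            scores[g] = a * b
        out[fid] = scores
    return out


def oracle_exhaustive_p(matrix, labels, statistic="max"):
    """Enumerate every two-group assignment; p = fraction with stat >= observed."""
    groups = sorted(set(labels.values()))
    n0 = sum(1 for s in labels if labels[s] == groups[0])
    samples = list(matrix.columns)
    obs_scores = oracle_scores(matrix, labels)
    obs = {f: max(s.values()) for f, s in obs_scores.items()}
    best_group = {f: min([g for g in groups if s[g] == max(s.values())]) for f, s in obs_scores.items()}
    counts = {f: 0 for f in matrix.index}
    total = 0
    for combo in combinations(samples, n0):
        lab = {s: groups[0] if s in combo else groups[1] for s in samples}
        scores = oracle_scores(matrix, lab)
        total += 1
        for f in matrix.index:
            stat = (
                max(scores[f].values())
                if statistic == "max"
                else scores[f][best_group[f]]
            )
            if stat >= obs[f] - 1e-12:
                counts[f] += 1
    return {f: counts[f] / total for f in matrix.index}


class TestIndvalScores:
    def test_perfect_indicator_scores_one(self):
        m, g = toy_matrix()
        scores = indval_scores(m, g)
        assert scores.loc["conc", "indval"] == pytest.approx(1.0)
        assert scores.loc["conc", "group"] == "A"

    def test_symmetric_feature_scores_half_in_both_groups(self):
        m, g = toy_matrix()
        scores = indval_scores(m, g)
        assert scores.loc["flat", "indval_A"] == pytest.approx(0.5)
        assert scores.loc["flat", "indval_B"] == pytest.approx(0.5)
        assert bool(scores.loc["flat", "tied"])

    def test_matches_hand_computed_oracle_on_random_matrix(self, rng):
        m = pd.DataFrame(
            rng.lognormal(1, 1, (12, 6)) * (rng.random((12, 6)) < 0.7),
            index=[f"f{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(6)],
        )
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=m.columns)
        scores = indval_scores(m, g)
        expected = oracle_scores(m, dict(g))
        for fid in m.index:
            assert scores.loc[fid, "indval_A"] == pytest.approx(expected[fid]["A"])
            assert scores.loc[fid, "indval_B"] == pytest.approx(expected[fid]["B"])

    def test_specificities_sum_to_one_and_absent_features_flagged(self, rng):
        m = pd.DataFrame(
            rng.lognormal(1, 1, (8, 6)) * (rng.random((8, 6)) < 0.6),
            columns=[f"s{j}" for j in range(6)],
        )
        m.iloc[3] = 0.0
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=m.columns)
        scores = indval_scores(m, g)
        means_a = m.loc[:, g == "A"].mean(axis=1)
        means_b = m.loc[:, g == "B"].mean(axis=1)
        present = (means_a + means_b) > 0
        assert bool(scores.loc[3, "absent"])
        assert scores.loc[3, "indval"] == 0.0
        # A_A + A_B = 1 is visible through scores at full presence
        full = m.gt(0).all(axis=1) & present
        if full.any():
            sub = scores.loc[full]
            np.testing.assert_allclose(
                sub["indval_A"] + sub["indval_B"], 1.0, rtol=1e-9
            )

    @given(st.floats(min_value=0.1, max_value=1000.0))
    @settings(max_examples=30, deadline=None)
    def test_scores_invariant_to_global_rescaling(self, k):
        m, g = toy_matrix()
        base = indval_scores(m, g)
        scaled = indval_scores(m * k, g)
        np.testing.assert_allclose(
            base[["indval_A", "indval_B"]].to_numpy(),
            scaled[["indval_A", "indval_B"]].to_numpy(),
            rtol=1e-9,
        )

    def test_negative_abundance_rejected(self):
        m, g = toy_matrix()
        m.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            indval_scores(m, g)


class TestIndvalSignificance:
    def test_exhaustive_matches_brute_force_oracle(self, rng):
        for statistic in ("max", "group"):
            m = pd.DataFrame(
                rng.lognormal(1, 1, (6, 6)) * (rng.random((6, 6)) < 0.7),
                index=[f"f{i}" for i in range(6)],
                columns=[f"s{j}" for j in range(6)],
            )
            g = pd.Series(["A"] * 3 + ["B"] * 3, index=m.columns)
            got = indval_significance(m, g, n_permutations=1000, statistic=statistic)
            assert (got["method"] == "exhaustive").all()
            expected = oracle_exhaustive_p(m, dict(g), statistic)
            for fid in m.index:
                assert got.loc[fid, "p_value"] == pytest.approx(expected[fid])

    def test_concentrated_toy_exhaustive_p_value(self):
        # 2+2 perfect indicator: the identity assignment and its
        # complement both attain the maximal score, so 2 of the
        # C(4,2)=6 assignments tie the observed statistic
        m, g = toy_matrix()
        got = indval_significance(m, g, n_permutations=1000)
        assert got.loc["conc", "p_value"] == pytest.approx(2 / 6)
        expected = oracle_exhaustive_p(m, dict(g))
        assert got.loc["conc", "p_value"] == pytest.approx(expected["conc"])

    def test_constant_feature_has_p_one(self):
        m, g = toy_matrix()
        got = indval_significance(m, g, n_permutations=1000)
        assert got.loc["flat", "p_value"] == pytest.approx(1.0)

    def test_monte_carlo_is_deterministic_under_seed_and_p_bounded(self, rng):
        table = generate_feature_table(
            FeatureTableConfig(n_features=25, n_samples_per_group=8, seed=5)
        )
        a = indval_significance(table.abundances, table.groups, 99, seed=3)
        b = indval_significance(table.abundances, table.groups, 99, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert (a["method"] == "montecarlo").all()
        assert (a["p_value"] >= 1 / 100).all()

    def test_null_rejection_rate_near_alpha_for_max_statistic(self):
        tot = sig = 0
        for seed in range(6):
            table = generate_feature_table(
                FeatureTableConfig(
                    n_features=150, n_samples_per_group=8, n_planted_indicators=0,
                    seed=seed,
                )
            )
            res = indval_significance(
                table.abundances, table.groups, n_permutations=499, seed=seed
            )
            tot += len(res)
            sig += int((res["p_value"] <= 0.05).sum())
        frac = sig / tot
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / tot)

    def test_planted_indicators_found_significant(self):
        table = generate_feature_table(
            FeatureTableConfig(
                n_features=60, n_samples_per_group=6, n_planted_indicators=5, seed=2
            )
        )
        res = indval_significance(
            table.abundances, table.groups, n_permutations=999, seed=0
        )
        planted = res.loc[table.planted["feature_id"]]
        assert (planted["p_value"] <= 0.05).mean() >= 0.8
        assert (
            planted["group"].to_numpy() == table.planted["group"].to_numpy()
        ).mean() >= 0.9

    def test_benjamini_hochberg_option_monotone(self, rng):
        table = generate_feature_table(
            FeatureTableConfig(n_features=40, n_samples_per_group=5, seed=8)
        )
        res = indval_significance(
            table.abundances, table.groups, 199, seed=1, adjust="bh"
        )
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        assert (res["p_adjusted"] <= 1.0).all()

    def test_single_sample_group_rejected(self):
        m, g = toy_matrix()
        g2 = pd.Series(["A", "B", "B", "B"], index=m.columns)
        with pytest.raises(ValueError, match="2 samples"):
            indval_significance(m, g2)

    def test_estimator_wrapper(self):
        table = generate_feature_table(
            FeatureTableConfig(n_features=15, n_samples_per_group=4, seed=9)
        )
        est = IndicatorValueAnalysis(n_permutations=99, random_state=0).fit(
            table.abundances.T, table.groups.to_numpy()
        )
        assert len(est.results_) == 15
        assert "p_value" in est.results_


class TestAggregateByClass:
    def test_counts_and_unclassified_binning(self):
        m, g = toy_matrix()
        res = indval_significance(m, g, n_permutations=1000)
        res = res.copy()
        res["p_value"] = [0.01, 0.01, 1.0]  # force the first two significant
        class_map = pd.DataFrame(
            {"feature_id": ["conc"], "level1_class": ["Metabolism"]}
        )
        agg = aggregate_by_class(res, class_map, m, g)
        assert set(agg["class"]) == {"Metabolism", "unclassified"}
        assert agg["n_indicators"].sum() == 2

    def test_no_significant_features_gives_empty_table(self):
        m, g = toy_matrix()
        res = indval_significance(m, g, n_permutations=1000)
        res["p_value"] = 1.0
        agg = aggregate_by_class(res, {}, m, g)
        assert agg.empty

    def test_planted_indicator_classes_dominate_counts(self):
        table = generate_feature_table(
            FeatureTableConfig(
                n_features=80, n_samples_per_group=6, n_planted_indicators=8, seed=4
            )
        )
        res = indval_significance(
            table.abundances, table.groups, n_permutations=499, seed=0
        )
        agg = aggregate_by_class(res, table.class_map, table.abundances, table.groups)
        planted_classes = set(
            table.class_map.set_index("feature_id")
            .loc[table.planted["feature_id"], "level1_class"]
        )
        assert agg["n_indicators"].sum() > 0
        assert set(agg.loc[agg["n_indicators"] > 0, "class"]) <= planted_classes | {
            "unclassified"
        } | set(table.class_map["level1_class"])


class TestRarefiedRichness:
    def test_full_depth_returns_observed_richness(self):
        counts = np.array([5, 0, 3, 2])
        assert rarefied_richness(counts, depth=10) == pytest.approx(3.0)

    def test_forced_inclusion_of_all_taxa(self):
        assert rarefied_richness([1, 1999], depth=2000) == pytest.approx(2.0)

    def test_matches_monte_carlo_oracle(self, rng):
        counts = np.concatenate([rng.integers(0, 40, 25), [1, 1, 2, 3, 2500]])
        rng.shuffle(counts)  # rare taxa keep the subsample richness variable
        expected = rarefied_richness(counts, depth=2000)
        pool = np.repeat(np.arange(counts.size), counts)
        draws = [
            np.unique(rng.choice(pool, 2000, replace=False)).size for _ in range(2000)
        ]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(expected - np.mean(draws)) < 3 * se + 1e-9

    def test_shallow_sample_and_bad_counts_rejected(self):
        with pytest.raises(ValueError, match="fewer than depth"):
            rarefied_richness([10, 10], depth=2000)
        with pytest.raises(ValueError, match="integer"):
            rarefied_richness([1.5, 2.5], depth=2)
        with pytest.raises(ValueError):
            rarefied_richness([-1, 10], depth=2)
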