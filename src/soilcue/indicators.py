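"""Indicator-value (IndVal) analysis, class roll-ups, rarefied richness.

For a features × samples abundance matrix with two sample groups (the
low- and high-intensity members of a land-use contrast), the IndVal
score of feature *i* for group *j* is the product of

* specificity ``A_ij`` — mean abundance of *i* in *j* divided by the
  sum of its group mean abundances, and
* fidelity ``B_ij`` — the fraction of group-*j* samples where *i* is
  present (abundance > 0),

so ``IndVal = A × B ∈ [0, 1]`` (some software scales by 100 for
display; scores here stay on the 0–1 scale). Each feature is assigned
the group attaining its maximal score. Significance comes from random
reassignment of the group labels (jointly across features, preserving
feature correlation): the default test statistic is the feature's
maximal score over groups, compared between observed and permuted
labellings — the classic indicator-species-analysis test, which is an
exact permutation test under group exchangeability. When the number of
distinct label assignments is no larger than the permutation budget the
test enumerates all of them instead of sampling.

``statistic="group"`` is also available: the permuted score of the
feature's *observed* best group. It reproduces intuitive per-group
p-values but, because the group is chosen from the data, it is
anticonservative under the null (for two groups roughly
``P(p ≤ α) ≈ 1 − (1 − α)²``); the default is therefore ``"max"``.

:func:`rarefied_richness` gives the expected number of taxa observed
in a random subsample of fixed depth (default 2000 reads) via the
hypergeometric closed form.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

__all__ = [
    "IndicatorValueAnalysis",
    "aggregate_by_class",
    "indval_scores",
    "indval_significance",
    "rarefied_richness",
]


def _validate_matrix(matrix: pd.DataFrame, groups: pd.Series):
    abund = matrix.to_numpy(dtype=float)
    if np.any(abund < 0):
        raise ValueError("abundances must be non-negative")
    groups = pd.Series(groups)
    if len(groups) != matrix.shape[1]:
        raise ValueError("one group label per sample column is required")
    if groups.isna().any():
        raise ValueError("every sample must be labelled")
    labels = sorted(pd.unique(groups.astype(str)))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    return abund, np.asarray(groups.astype(str)), labels


def _score_matrix(abund: np.ndarray, group_masks: list[np.ndarray]) -> np.ndarray:
    """IndVal scores, shape (n_features, n_groups)."""
    means = np.stack([abund[:, m].mean(axis=1) for m in group_masks], axis=1)
    total = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / np.where(total > 0, total, 1.0), 0.0)
    b = np.stack([(abund[:, m] > 0).mean(axis=1) for m in group_masks], axis=1)
    return a * b


def indval_scores(matrix: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-feature, per-group IndVal scores with the assigned group.

    Returns a frame indexed like ``matrix`` with one ``indval_<group>``
    column per group, the assigned ``group`` (argmax; ties go to the
    lexicographically first group and set ``tied``), the assigned
    ``indval`` score, and an ``absent`` flag for features with zero
    total abundance (scored 0 everywhere).
    """
    abund, glabels, labels = _validate_matrix(matrix, groups)
    masks = [glabels == g for g in labels]
    scores = _score_matrix(abund, masks)
    out = pd.DataFrame(
        {f"indval_{g}": scores[:, j] for j, g in enumerate(labels)},
        index=matrix.index,
    )
    best = scores.argmax(axis=1)  # argmax returns the first (lexicographic) max
    out["group"] = [labels[j] for j in best]
    out["indval"] = scores[np.arange(len(best)), best]
    sorted_scores = np.sort(scores, axis=1)
    out["tied"] = (scores.shape[1] > 1) & (
        sorted_scores[:, -1] == sorted_scores[:, -2]
    ) & (out["indval"].to_numpy() > 0)
    out["absent"] = abund.sum(axis=1) == 0
    return out


def indval_significance(
    matrix: pd.DataFrame,
    groups,
    n_permutations: int = 1000,
    seed: int | None = None,
    *,
    statistic: str = "max",
    adjust: str | None = None,
) -> pd.DataFrame:
    """IndVal scores with permutation p-values.

    Group labels are permuted jointly across features. With the default
    ``statistic="max"`` the per-feature test statistic is its maximal
    score over groups; ``statistic="group"`` uses the permuted score of
    the observed best group (see the module docstring for the
    trade-off). Monte-Carlo p-values use the add-one estimator
    ``(1 + #{permuted ≥ observed}) / (n_permutations + 1)`` so p is
    never 0; when the number of distinct two-group label assignments is
    ≤ ``n_permutations`` every assignment is enumerated once and the
    p-value is the exact proportion (the identity assignment counts, so
    p ≥ 1/#assignments). Deterministic under a fixed ``seed``.

    ``adjust="bh"`` appends a Benjamini–Hochberg ``p_adjusted`` column
    (off by default; the study reports per-feature permutation
    significance).
    """
    if statistic not in ("max", "group"):
        raise ValueError("statistic must be 'max' or 'group'")
    abund, glabels, labels = _validate_matrix(matrix, groups)
    counts = [int((glabels == g).sum()) for g in labels]
    if min(counts) < 2:
        raise ValueError("need at least 2 samples per group")
    scores = indval_scores(matrix, groups)
    best_idx = np.array([labels.index(g) for g in scores["group"]])
    n_feat = abund.shape[0]
    observed = scores["indval"].to_numpy()

    n_samples = abund.shape[1]
    exhaustive = (
        len(labels) == 2 and comb(n_samples, counts[0]) <= n_permutations
    )

    def stat_for(perm_labels: np.ndarray) -> np.ndarray:
        masks = [perm_labels == g for g in labels]
        s = _score_matrix(abund, masks)
        if statistic == "max":
            return s.max(axis=1)
        return s[np.arange(n_feat), best_idx]

    if exhaustive:
        total = comb(n_samples, counts[0])
        ge = np.zeros(n_feat)
        base = np.array([labels[1]] * n_samples, dtype=object)
        for idx in combinations(range(n_samples), counts[0]):
            perm = base.copy()
            perm[list(idx)] = labels[0]
            ge += stat_for(perm) >= observed - 1e-12
        pvals = ge / total
        n_used = total
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        ge = np.zeros(n_feat)
        for _ in range(n_permutations):
            perm = rng.permutation(glabels)
            ge += stat_for(perm) >= observed - 1e-12
        pvals = (1.0 + ge) / (n_permutations + 1.0)
        n_used = n_permutations
        method = "montecarlo"

    out = scores.copy()
    out["p_value"] = pvals
    out["n_permutations"] = n_used
    out["method"] = method
    if adjust is not None:
        if adjust != "bh":
            raise ValueError("adjust must be None or 'bh'")
        out["p_adjusted"] = _benjamini_hochberg(pvals)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def aggregate_by_class(
    results: pd.DataFrame,
    class_map,
    matrix: pd.DataFrame,
    groups,
    *,
    alpha: float = 0.05,
    class_col: str = "level1_class",
) -> pd.DataFrame:
    """Roll significant indicators up into functional classes.

    For each (group, class): the count of significant indicator
    features (``p_value ≤ alpha``) assigned to the group, and the sum
    of their in-group mean relative abundances (each feature's mean
    abundance in the group divided by the group's total mean abundance
    across all features). Features without a class entry are binned as
    ``"unclassified"``. Returns an empty frame when nothing is
    significant.
    """
    abund, glabels, labels = _validate_matrix(matrix, groups)
    if isinstance(class_map, pd.DataFrame):
        mapping = dict(zip(class_map["feature_id"].astype(str), class_map[class_col]))
    else:
        mapping = dict(class_map)

    group_mean = {
        g: pd.Series(abund[:, glabels == g].mean(axis=1), index=matrix.index)
        for g in labels
    }
    sig = results[results["p_value"] <= alpha]
    rows = []
    for g in labels:
        sub = sig[sig["group"] == g]
        if sub.empty:
            continue
        total = float(group_mean[g].sum())
        classes = [str(mapping.get(str(fid), "unclassified")) for fid in sub.index]
        frame = pd.DataFrame(
            {
                "class": classes,
                "rel_abundance": (
                    group_mean[g].loc[sub.index] / total if total > 0 else 0.0
                ),
            }
        )
        agg = frame.groupby("class").agg(
            n_indicators=("class", "size"), rel_abundance_sum=("rel_abundance", "sum")
        )
        for cls, row in agg.iterrows():
            rows.append(
                {
                    "group": g,
                    "class": cls,
                    "n_indicators": int(row["n_indicators"]),
                    "rel_abundance_sum": float(row["rel_abundance_sum"]),
                }
            )
    return pd.DataFrame(rows, columns=["group", "class", "n_indicators", "rel_abundance_sum"])


def rarefied_richness(counts, depth: int = 2000) -> float:
    """Expected taxon richness in a random subsample of ``depth`` reads.

    Hypergeometric closed form: for total reads ``N`` and per-taxon
    counts ``n_i``, the expected richness is
    ``Σ_i [1 − C(N − n_i, depth) / C(N, depth)]`` — deterministic, no
    resampling. Raises ``ValueError`` when the sample has fewer than
    ``depth`` reads (callers should flag such samples instead of
    rarefying them).
    """
    counts = np.asarray(counts)
    if counts.size and not np.issubdtype(counts.dtype, np.integer):
        as_int = counts.astype(np.int64)
        if np.any(as_int != counts):
            raise ValueError("counts must be non-negative integers")
        counts = as_int
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative integers")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample has {total} reads, fewer than depth {depth}")
    nz = counts[counts > 0].astype(np.int64)

    def ln_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - nz
    prob_missing = np.where(
        rest >= depth,
        np.exp(ln_choose(rest, depth) - ln_choose(total, depth)),
        0.0,
    )
    return float(np.sum(1.0 - prob_missing))


class IndicatorValueAnalysis(BaseEstimator):
    """sklearn-style wrapper for the IndVal permutation analysis.

    ``fit(X, y)`` takes ``X`` as samples × features (sklearn
    orientation; transposed internally) and ``y`` as the per-sample
    group labels. Fitted attributes: ``scores_`` (per-feature,
    per-group scores) and ``results_`` (scores with permutation
    p-values).
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        statistic: str = "max",
        random_state: int | None = None,
    ):
        self.n_permutations = n_permutations
        self.statistic = statistic
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            matrix = X.T
        else:
            X = np.asarray(X, dtype=float)
            matrix = pd.DataFrame(
                X.T,
                index=[f"F{i + 1:04d}" for i in range(X.shape[1])],
                columns=[f"s{j + 1}" for j in range(X.shape[0])],
            )
        groups = pd.Series(np.asarray(y), index=matrix.columns)
        self.scores_ = indval_scores(matrix, groups)
        self.results_ = indval_significance(
            matrix,
            groups,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            statistic=self.statistic,
        )
        return self
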