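"""Land-use intensification contrasts: fold changes and effect types.

Each contrast pairs a low-intensity site (typically unimproved
permanent grassland) with a nearby high-intensity one (fertilised
intensive grassland or arable cropland). The effect of intensification
on a trait is summarised as a fold change — the ratio of the
high-intensity to the low-intensity mean (>1 means the trait increased
on intensification) — and each pair is classified by where its mean
soil pH sits relative to the pH threshold:

* Type 1: both members above the threshold;
* Type 2: intensification carries pH across the threshold (low member
  at or below, high member above);
* Type 3: both members at or below the threshold.

A reversed pair (high member at/below, low member above) is flagged
unclassified. A transcription of the survey's 21 contrast pairs (mean
pH and soil C of each member) ships with the package; see
:func:`load_contrast_table`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "classify_contrast",
    "classify_pairs",
    "fold_change",
    "load_contrast_table",
    "summarize_by_type",
    "summarize_contrasts",
]

DEFAULT_PH_THRESHOLD = 6.2


def classify_contrast(ph_low: float, ph_high: float, threshold: float) -> int | None:
    """Classify one pair into effect Type 1/2/3 by mean member pH.

    pH exactly at the threshold counts as below-or-equal (so a pair
    whose high-intensity member sits exactly at the threshold is
    Type 3). Returns ``None`` for a de-intensification reversal
    (``ph_high ≤ threshold < ph_low``).
    """
    if not (np.isfinite(ph_low) and np.isfinite(ph_high)):
        raise ValueError("pH values must be finite")
    low_above = ph_low > threshold
    high_above = ph_high > threshold
    if low_above and high_above:
        return 1
    if not low_above and high_above:
        return 2
    if not low_above and not high_above:
        return 3
    return None


def fold_change(low_values, high_values) -> float:
    """Intensification fold change: mean(high) / mean(low).

    Values above 1 mean the trait increased on intensification. NaN
    (undefined) when the low-intensity mean is zero.
    """
    low = np.asarray(low_values, dtype=float)
    high = np.asarray(high_values, dtype=float)
    if low.size == 0 or high.size == 0:
        raise ValueError("both members need at least one value")
    ml = np.nanmean(low)
    if ml == 0:
        return float("nan")
    return float(np.nanmean(high) / ml)


def load_contrast_table() -> pd.DataFrame:
    """Load the packaged 21-pair contrast table.

    Columns: ``pair_id``, ``region``, per-member management
    description, mean soil pH (``ph_low``/``ph_high``) and mean soil C
    % (``c_low``/``c_high``).
    """
    ref = resources.files("soilcue.data").joinpath("land_use_contrasts.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def classify_pairs(
    pairs: pd.DataFrame, threshold: float = DEFAULT_PH_THRESHOLD
) -> pd.DataFrame:
    """Classify a pair-level table (``ph_low``/``ph_high`` columns).

    Returns a copy with a ``type`` column (pandas nullable Int64;
    reversals are <NA>) and, when ``c_low``/``c_high`` are present, the
    soil-C fold change ``fc_c_pct``.
    """
    out = pairs.copy()
    out["type"] = pd.array(
        [classify_contrast(lo, hi, threshold) for lo, hi in zip(out["ph_low"], out["ph_high"])],
        dtype="Int64",
    )
    if {"c_low", "c_high"}.issubset(out.columns):
        out["fc_c_pct"] = [
            fold_change([lo], [hi]) for lo, hi in zip(out["c_low"], out["c_high"])
        ]
    return out


def summarize_contrasts(
    traits: pd.DataFrame,
    threshold: float = DEFAULT_PH_THRESHOLD,
    trait_names: tuple = ("cue", "turnover", "qco2", "enzyme_investment", "c_pct"),
) -> pd.DataFrame:
    """Per-pair contrast summary from a replicate-level traits table.

    The table needs ``pair_id``, ``intensity`` (``low``/``high``),
    ``ph`` and the trait columns. Member means are taken over
    non-missing replicate values (site-mean aggregation); each pair row
    reports its mean member pH values, effect type, replicate counts
    and per-trait fold changes (``fc_<trait>``).
    """
    required = {"pair_id", "intensity", "ph"}
    missing = required - set(traits.columns)
    if missing:
        raise KeyError(f"traits table is missing columns {sorted(missing)}")
    rows = []
    for pair_id, grp in traits.groupby("pair_id", sort=True):
        low = grp[grp["intensity"] == "low"]
        high = grp[grp["intensity"] == "high"]
        if low.empty or high.empty:
            raise ValueError(f"pair '{pair_id}' lacks a low or high member")
        ph_low = float(low["ph"].mean())
        ph_high = float(high["ph"].mean())
        row = {
            "pair_id": pair_id,
            "type": classify_contrast(ph_low, ph_high, threshold),
            "ph_low": ph_low,
            "ph_high": ph_high,
            "n_low": int(low["ph"].count()),
            "n_high": int(high["ph"].count()),
        }
        for trait in trait_names:
            if trait not in grp.columns:
                continue
            lo_vals = low[trait].dropna().to_numpy()
            hi_vals = high[trait].dropna().to_numpy()
            row[f"fc_{trait}"] = (
                fold_change(lo_vals, hi_vals)
                if lo_vals.size and hi_vals.size
                else float("nan")
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["type"] = pd.array(out["type"], dtype="Int64")
    return out


def summarize_by_type(summaries: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style fold-change statistics per effect type and trait.

    For every (type, trait) with at least one finite fold change:
    count, mean, median, first/third quartile, min and max. Empty types
    are omitted.
    """
    fc_cols = [c for c in summaries.columns if c.startswith("fc_")]
    rows = []
    for t, grp in summaries.dropna(subset=["type"]).groupby("type", sort=True):
        for col in fc_cols:
            vals = grp[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append(
                {
                    "type": int(t),
                    "trait": col[3:],
                    "n_contrasts": int(vals.size),
                    "mean": float(np.mean(vals)),
                    "median": float(np.median(vals)),
                    "q1": float(np.percentile(vals, 25)),
                    "q3": float(np.percentile(vals, 75)),
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                }
            )
    return pd.DataFrame(rows)
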