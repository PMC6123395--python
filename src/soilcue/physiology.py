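"""Community ecophysiological traits from incubation and isotope data.

One soil replicate contributes a small set of raw measurements: total
extractable DNA carbon (``dna_c``, a microbial-biomass proxy, µg C g⁻¹
soil), the excess ``13C`` recovered in DNA and in cumulatively respired
CO₂ after an overnight (16 h) incubation with a ``13C``-labelled
dissolved-organic-carbon substrate, basal respiration (µg C g⁻¹ h⁻¹)
and a potential extracellular-enzyme activity. From these the module
derives the community traits used throughout the package:

======================  ==================================================
carbon use efficiency   CUE = DNA-¹³C / (DNA-¹³C + ΣCO₂-¹³C)
turnover (growth) rate  DNA-¹³C / DNA-C, per 16-h incubation
metabolic quotient      qCO₂ = basal respiration / DNA-C
enzyme investment       enzyme activity / DNA-C
======================  ==================================================

Raw isotope-ratio measurements in δ notation can be converted to atom
fractions and label (tracer) fractions with :func:`delta_to_atom_fraction`
and :func:`label_fraction`; the trait formulas themselves take
label-derived excess masses.

Traits that are undefined for a replicate (e.g. ``dna_c == 0``) are
flagged, never dropped, so downstream sample counts stay auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "IsotopeConstants",
    "SURVEY_COLUMNS",
    "TRAIT_COLUMNS",
    "SchemaError",
    "TraitCalculator",
    "compute_cue",
    "compute_enzyme_investment",
    "compute_qco2",
    "compute_turnover",
    "delta_to_atom_fraction",
    "derive_traits",
    "label_fraction",
    "validate_survey",
]

#: Column schema of a survey table, one row per soil replicate.
SURVEY_COLUMNS = [
    "site_id",
    "pair_id",
    "intensity",
    "ph",
    "moisture_pct",
    "clay_pct",
    "c_pct",
    "n_pct",
    "loi_pct",
    "dna_c",
    "dna_13c_excess",
    "co2_13c_excess",
    "basal_resp",
    "enzyme_activity",
]

#: Columns strictly required to derive traits.
_REQUIRED = [
    "site_id",
    "ph",
    "c_pct",
    "n_pct",
    "dna_c",
    "dna_13c_excess",
    "co2_13c_excess",
    "basal_resp",
    "enzyme_activity",
]

TRAIT_COLUMNS = ["cue", "turnover", "qco2", "enzyme_investment", "cn_ratio"]

# Natural-abundance 13C atom fraction of a C3-plant/soil carbon pool
# (δ ≈ −27 ‰ vs VPDB); used as the default unlabelled background.
_VPDB_R = 0.0111802


class SchemaError(ValueError):
    """A survey table is missing required columns or has invalid values."""


@dataclass(frozen=True)
class IsotopeConstants:
    """Constants for converting δ values to label fractions.

    Parameters
    ----------
    r_standard :
        ``13C/12C`` isotope ratio of the reference standard (VPDB).
    af_background :
        Atom fraction of the unlabelled background pool. Default is the
        atom fraction of a δ = −27 ‰ (C3 plant / soil organic matter)
        pool.
    af_label :
        Atom fraction of the label source. The tracer substrate is a
        low-enrichment plant litter at roughly one atom-percent excess
        above natural abundance, so the default is
        ``af_background + 0.01``.
    """

    r_standard: float = _VPDB_R
    af_background: float = _VPDB_R * (1.0 - 0.027) / (1.0 + _VPDB_R * (1.0 - 0.027))
    af_label: float = _VPDB_R * (1.0 - 0.027) / (1.0 + _VPDB_R * (1.0 - 0.027)) + 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.af_background < self.af_label <= 1.0):
            raise ValueError(
                "require 0 < af_background < af_label <= 1; got "
                f"af_background={self.af_background}, af_label={self.af_label}"
            )
        if self.r_standard <= 0:
            raise ValueError("r_standard must be positive")


def delta_to_atom_fraction(delta_permil, constants: IsotopeConstants | None = None):
    """Convert a δ value (‰ vs the standard) to a ``13C`` atom fraction.

    ``R = r_standard * (δ/1000 + 1)`` and the atom fraction is
    ``R / (1 + R)``; strictly increasing in δ.

    Raises
    ------
    ValueError
        If ``δ ≤ −1000`` (an isotope ratio cannot be negative).
    """
    constants = constants or IsotopeConstants()
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta values must be > -1000 permil")
    r = constants.r_standard * (delta / 1000.0 + 1.0)
    af = r / (1.0 + r)
    return af if af.ndim else float(af)


def label_fraction(
    af_sample,
    constants: IsotopeConstants | None = None,
    *,
    rtol: float = 1e-6,
):
    """Fraction of a pool's carbon derived from the label source.

    Two-pool linear mixing between the unlabelled background and the
    label source:
    ``(af_sample − af_background) / (af_label − af_background)``.

    Samples outside ``[af_background, af_label]`` by at most
    ``rtol * (af_label − af_background)`` are clipped into range with a
    warning; larger excursions raise ``ValueError``.
    """
    constants = constants or IsotopeConstants()
    af = np.asarray(af_sample, dtype=float)
    lo, hi = constants.af_background, constants.af_label
    span = hi - lo
    tol = rtol * span
    if np.any(af < lo - tol) or np.any(af > hi + tol):
        raise ValueError(
            f"atom fraction outside [{lo}, {hi}] beyond tolerance {tol}"
        )
    if np.any(af < lo) or np.any(af > hi):
        warnings.warn(
            "atom fraction marginally outside the mixing interval; clipping",
            stacklevel=2,
        )
        af = np.clip(af, lo, hi)
    frac = (af - lo) / span
    return frac if frac.ndim else float(frac)


def _ratio(num, den, num_name: str, den_name: str):
    """Elementwise num/den with NaN (undefined flag) where den == 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if np.any(num < 0) or np.any(den < 0):
        raise ValueError(f"{num_name} and {den_name} must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def compute_cue(dna_13c_excess, co2_13c_excess):
    """Carbon use efficiency: DNA-¹³C / (DNA-¹³C + ΣCO₂-¹³C).

    The fraction of assimilated label carbon allocated to biomass (DNA)
    rather than respired. Returns NaN (undefined) where both inputs are
    zero.
    """
    dna = np.asarray(dna_13c_excess, dtype=float)
    co2 = np.asarray(co2_13c_excess, dtype=float)
    out = _ratio(dna, dna + co2, "dna_13c_excess", "dna_13c_excess+co2_13c_excess")
    return out if out.ndim else float(out)


def compute_turnover(dna_13c_excess, dna_c):
    """Turnover (growth) rate: DNA-¹³C / DNA-C, per incubation period.

    The fraction of the DNA-carbon pool newly synthesised from the
    labelled substrate over the 16-h incubation. NaN where
    ``dna_c == 0``.
    """
    dna13 = np.asarray(dna_13c_excess, dtype=float)
    dnac = np.asarray(dna_c, dtype=float)
    if np.any(dna13 > dnac * (1 + 1e-12)):
        raise ValueError("dna_13c_excess cannot exceed dna_c")
    out = _ratio(dna13, dnac, "dna_13c_excess", "dna_c")
    return out if out.ndim else float(out)


def compute_qco2(basal_resp, dna_c):
    """Metabolic quotient qCO₂: basal respiration per unit DNA-C."""
    out = _ratio(basal_resp, dna_c, "basal_resp", "dna_c")
    return out if out.ndim else float(out)


def compute_enzyme_investment(enzyme_activity, dna_c):
    """Extracellular enzyme activity per unit DNA-C."""
    out = _ratio(enzyme_activity, dna_c, "enzyme_activity", "dna_c")
    return out if out.ndim else float(out)


def validate_survey(table: pd.DataFrame, *, required=None) -> None:
    """Check a survey table against the replicate schema.

    Raises :class:`SchemaError` naming the first missing column, or
    describing an out-of-range value (pH outside (0, 14), negative
    masses/rates, percentages outside [0, 100], label carbon in DNA
    exceeding total DNA carbon).
    """
    required = _REQUIRED if required is None else required
    for col in required:
        if col not in table.columns:
            raise SchemaError(f"survey table is missing required column '{col}'")
    if len(table) == 0:
        return
    ph = table["ph"].to_numpy(dtype=float)
    if np.any((ph <= 0) | (ph >= 14)):
        raise SchemaError("ph must lie in (0, 14)")
    for col in ("moisture_pct", "clay_pct", "c_pct", "n_pct", "loi_pct"):
        if col in table.columns:
            v = table[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 100)):
                raise SchemaError(f"{col} must lie in [0, 100]")
    for col in (
        "dna_c",
        "dna_13c_excess",
        "co2_13c_excess",
        "basal_resp",
        "enzyme_activity",
    ):
        v = table[col].to_numpy(dtype=float)
        if np.any(v < 0):
            raise SchemaError(f"{col} must be non-negative")
    if np.any(
        table["dna_13c_excess"].to_numpy(dtype=float)
        > table["dna_c"].to_numpy(dtype=float) * (1 + 1e-12)
    ):
        raise SchemaError("dna_13c_excess cannot exceed dna_c")


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the trait set for every replicate of a survey table.

    Returns a table with the replicate keys (``site_id`` and, when
    present, ``pair_id``/``intensity``/``ph``/``c_pct``), the trait
    columns ``cue``, ``turnover``, ``qco2``, ``enzyme_investment``,
    ``cn_ratio``, and a ``flags`` column listing any traits that were
    undefined for that replicate (NaN in the trait column). Row count
    equals the input row count.
    """
    validate_survey(table)
    keys = [c for c in ("site_id", "pair_id", "intensity", "ph", "c_pct") if c in table]
    out = table[keys].copy().reset_index(drop=True)
    dna13 = table["dna_13c_excess"].to_numpy(dtype=float)
    co213 = table["co2_13c_excess"].to_numpy(dtype=float)
    dnac = table["dna_c"].to_numpy(dtype=float)
    out["cue"] = compute_cue(dna13, co213)
    out["turnover"] = compute_turnover(dna13, dnac)
    out["qco2"] = compute_qco2(table["basal_resp"].to_numpy(dtype=float), dnac)
    out["enzyme_investment"] = compute_enzyme_investment(
        table["enzyme_activity"].to_numpy(dtype=float), dnac
    )
    out["cn_ratio"] = _ratio(
        table["c_pct"].to_numpy(dtype=float),
        table["n_pct"].to_numpy(dtype=float),
        "c_pct",
        "n_pct",
    )
    flag_cols = ["cue", "turnover", "qco2", "enzyme_investment", "cn_ratio"]
    flags = []
    nan_mask = {c: np.isnan(out[c].to_numpy(dtype=float)) for c in flag_cols}
    for i in range(len(out)):
        undef = [c for c in flag_cols if nan_mask[c][i]]
        flags.append(";".join(f"undefined:{c}" for c in undef))
    out["flags"] = flags
    return out


class TraitCalculator(TransformerMixin, BaseEstimator):
    """Stateless transformer wrapping :func:`derive_traits`.

    Provided so trait derivation composes with sklearn pipelines; ``fit``
    only validates the schema.
    """

    def fit(self, X: pd.DataFrame, y=None):
        validate_survey(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return derive_traits(X)
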