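"""Synthetic surveys, paired land-use contrasts and feature tables.

The generators emulate the study design the rest of the package
analyses: a landscape-scale survey of geographically dispersed sites
(default 56 sites × 3 replicates) whose microbial traits follow
regime-specific trait–SOC regression models with a switch at a
configurable soil-pH break; paired low/high-intensity land-use
contrasts with planted per-type trait fold changes; and two-group
feature-abundance tables with planted indicator features.

Planted traits are back-derived into raw measurements so that
:mod:`soilcue.physiology` recovers them exactly:

* ``DNA-¹³C = turnover × DNA-C``
* ``ΣCO₂-¹³C = DNA-¹³C × (1 − CUE)/CUE``
* ``basal respiration = qCO₂ × DNA-C``
* ``enzyme activity = investment × DNA-C``

Ground-truth columns (``true_*``, ``regime``) ride along in the
returned frames; :func:`write_survey` writes only the documented
survey schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from soilcue.physiology import SURVEY_COLUMNS

__all__ = [
    "DEFAULT_TRAIT_MODELS",
    "SurveyConfig",
    "ContrastConfig",
    "FeatureTableConfig",
    "FeatureTable",
    "generate_survey",
    "generate_contrasts",
    "generate_feature_table",
    "evaluate_form",
    "write_survey",
    "read_survey",
    "write_feature_table",
    "read_feature_table",
]

#: Generative trait–SOC models, keyed by trait then pH regime
#: ("below" / "above" the break, or "all" for regime-independent
#: traits).  Each entry is (form, a, b) with forms
#: linear: a·x + b, log: a·ln(x) + b, exponential: a·e^(b·x);
#: x is SOC in %.  These defaults are the survey's fitted
#: trait–SOC regressions and double as the generator's ground truth.
DEFAULT_TRAIT_MODELS: dict[str, dict[str, tuple[str, float, float]]] = {
    "cue": {"below": ("linear", 0.0004, 0.01), "above": ("linear", 0.01, 0.02)},
    "turnover": {"below": ("log", -0.02, 0.05), "above": ("log", -0.21, 0.55)},
    "qco2": {"all": ("exponential", 0.16, -0.12)},
    "dna_c": {"all": ("linear", 5.09, -0.07)},
    "enzyme_investment": {"all": ("log", -1.37, 4.87)},
    "richness": {"all": ("linear", 11.06, 962.0)},
}

_TRAITS = ("cue", "turnover", "qco2", "enzyme_investment")

# SOC (%) sampling per pH regime: acidic (often wetter) soils carry more
# organic carbon.  Lognormal medians/log-SD calibrated to the packaged
# land-use contrast table, whose below-threshold members span ~4-24 % C
# (median ~8) and above-threshold members ~1-16 % (median ~3).
_SOC_SAMPLER = {
    "below": {"median": 8.0, "sigma": 0.5, "lo": 1.5, "hi": 25.0},
    "above": {"median": 2.8, "sigma": 0.55, "lo": 0.5, "hi": 12.0},
}

#: Within-site replicate pH jitter (SD, pH units); small spatial
#: variation among the three cores of a site.
PH_JITTER_SD = 0.05


def evaluate_form(form: str, a: float, b: float, x):
    """Evaluate a trait–SOC functional form at SOC values ``x``."""
    x = np.asarray(x, dtype=float)
    if form == "linear":
        return a * x + b
    if form == "log":
        if np.any(x <= 0):
            raise ValueError("log form requires x > 0")
        return a * np.log(x) + b
    if form == "exponential":
        return a * np.exp(b * x)
    raise ValueError(f"unknown functional form '{form}'")


@dataclass(frozen=True)
class SurveyConfig:
    """Configuration of the synthetic landscape survey.

    ``noise_sd`` is the per-trait relative noise scale: strictly
    positive traits get multiplicative lognormal noise
    ``exp(N(0, noise_sd))``; CUE gets additive Gaussian noise of
    sd ``noise_sd * 0.05`` (a reference community CUE), truncated into
    (0, 1) — see :data:`CUE_NOISE_SCALE`.  Auxiliary soil
    variables (moisture, clay, C:N, LOI) carry noise proportional to
    ``noise_sd`` so that ``noise_sd = 0`` yields a fully deterministic
    trait structure (only site pH placement and replicate pH jitter
    remain random, controlled by ``seed``).
    """

    n_sites: int = 56
    reps_per_site: int = 3
    ph_range: tuple[float, float] = (3.5, 8.5)
    ph_break: float = 6.2
    noise_sd: float = 0.2
    seed: int = 0
    trait_models: dict = field(default_factory=lambda: DEFAULT_TRAIT_MODELS)

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.reps_per_site < 1:
            raise ValueError("reps_per_site must be >= 1")
        if not (self.ph_range[0] < self.ph_break < self.ph_range[1]):
            raise ValueError(
                f"ph_break {self.ph_break} must lie strictly inside "
                f"ph_range {self.ph_range}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ContrastConfig:
    """Configuration of paired low/high-intensity land-use contrasts.

    The three effect types are defined by where the pair's soil pH sits
    relative to ``ph_break``: Type 1 both members above, Type 2
    straddling (intensification raises pH across the break), Type 3 both
    at or below.  ``effect_directions`` plants per-trait fold-change
    directions per type; the defaults encode intensification lowering
    SOC everywhere, lowering biomass and raising turnover/qCO₂ above the
    break, CUE decreasing for Type 1 but increasing for Type 2, and only
    the SOC loss for Type 3.
    """

    n_pairs_per_type: tuple[int, int, int] = (11, 6, 4)
    effect_directions: dict = field(
        default_factory=lambda: {
            1: {
                "cue": "decrease",
                "turnover": "increase",
                "qco2": "increase",
                "dna_c": "decrease",
                "c_pct": "decrease",
            },
            2: {
                "cue": "increase",
                "turnover": "increase",
                "qco2": "increase",
                "dna_c": "decrease",
                "c_pct": "decrease",
            },
            3: {"c_pct": "decrease"},
        }
    )
    effect_size: float = 1.6
    reps_per_site: int = 3
    ph_range: tuple[float, float] = (3.5, 8.5)
    ph_break: float = 6.2
    noise_sd: float = 0.2
    seed: int = 0
    trait_models: dict = field(default_factory=lambda: DEFAULT_TRAIT_MODELS)

    def validate(self) -> None:
        if any(n < 0 for n in self.n_pairs_per_type):
            raise ValueError("pair counts must be >= 0")
        for t, dirs in self.effect_directions.items():
            if t not in (1, 2, 3):
                raise ValueError(f"unknown contrast type {t}")
            for trait, d in dirs.items():
                if d not in ("increase", "decrease", "none"):
                    raise ValueError(f"invalid direction '{d}' for {trait}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        lo, hi = self.ph_range
        # need head-room on both sides of the break to place pairs
        if not (lo + 0.2 < self.ph_break < hi - 0.3):
            raise ValueError(
                f"ph_break {self.ph_break} leaves no room inside ph_range "
                f"{self.ph_range} to place contrast pairs"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FeatureTableConfig:
    """Configuration of a two-group feature-abundance matrix.

    Emulates a metaproteomic spectral-abundance table for one land-use
    contrast: two groups (``low`` / ``high`` intensity) with
    ``n_samples_per_group`` samples each, lognormal abundances and
    Bernoulli presence for background (group-exchangeable) features, and
    ``n_planted_indicators`` features per group with elevated presence
    and abundance in their group.
    """

    n_features: int = 200
    n_samples_per_group: int = 3
    n_planted_indicators: int = 0
    abundance_mu: float = 2.0
    abundance_sigma: float = 1.0
    presence_prob_background: float = 0.6
    indicator_presence_in: float = 1.0
    indicator_presence_out: float = 0.1
    indicator_abundance_fold: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_features and n_samples_per_group must be >= 1")
        if 2 * self.n_planted_indicators > self.n_features:
            raise ValueError("planted indicators (both groups) exceed n_features")
        for p in (
            self.presence_prob_background,
            self.indicator_presence_in,
            self.indicator_presence_out,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("presence probabilities must lie in [0, 1]")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")


class FeatureTable(NamedTuple):
    """A features × samples abundance matrix with its sample groups."""

    abundances: pd.DataFrame
    groups: pd.Series
    class_map: pd.DataFrame
    planted: pd.DataFrame


def _regime(ph, ph_break: float):
    """'above' where ph > break; pH exactly at the break is 'below'."""
    return np.where(np.asarray(ph, dtype=float) > ph_break, "above", "below")


def _model_for(trait_models: dict, trait: str, regime: str):
    entry = trait_models[trait]
    return entry["all"] if "all" in entry else entry[regime]


def _planted_traits(soc, regimes, trait_models: dict) -> dict[str, np.ndarray]:
    """Noise-free trait values from the regime models, clipped to domain."""
    soc = np.asarray(soc, dtype=float)
    out: dict[str, np.ndarray] = {}
    for trait in _TRAITS + ("dna_c",):
        vals = np.empty_like(soc)
        for reg in ("below", "above"):
            mask = regimes == reg
            if not np.any(mask):
                continue
            form, a, b = _model_for(trait_models, trait, reg)
            vals[mask] = evaluate_form(form, a, b, soc[mask])
        out[trait] = vals
    # keep every trait inside its physical domain; the fitted log forms
    # can dip below zero at the SOC extremes
    out["cue"] = np.clip(out["cue"], 1e-4, 1.0 - 1e-4)
    out["turnover"] = np.clip(out["turnover"], 1e-3, 1.0 - 1e-3)
    out["qco2"] = np.maximum(out["qco2"], 1e-6)
    out["enzyme_investment"] = np.maximum(out["enzyme_investment"], 1e-3)
    out["dna_c"] = np.maximum(out["dna_c"], 0.05)
    return out


#: Reference CUE scale for the additive measurement-noise model: the
#: community CUE of a typical above-threshold soil.  Isotope-tracer CUE
#: estimates carry a roughly constant absolute error (the 13C-excess
#: signals, not the ratio, are what the instrument measures), so
#: low-CUE acidic soils have proportionally much noisier CUE.
CUE_NOISE_SCALE = 0.05


def _add_trait_noise(traits: dict[str, np.ndarray], noise_sd: float, rng) -> dict:
    if noise_sd == 0:
        return {k: v.copy() for k, v in traits.items()}
    noisy = {}
    for trait, vals in traits.items():
        if trait == "cue":
            # additive Gaussian on the CUE scale (sd = noise_sd times a
            # reference CUE), truncated into (0, 1): the 13C-excess
            # signals behind CUE carry a roughly constant absolute
            # error, and low-CUE values censor at the detection limit
            abs_sd = noise_sd * CUE_NOISE_SCALE
            noisy[trait] = np.clip(
                vals + rng.normal(0.0, abs_sd, size=vals.shape), 1e-4, 1.0 - 1e-4
            )
        else:
            noisy[trait] = vals * np.exp(rng.normal(0.0, noise_sd, size=vals.shape))
    noisy["turnover"] = np.clip(noisy["turnover"], 1e-4, 1.0 - 1e-4)
    return noisy


def _assemble_rows(
    *,
    site_ids,
    pair_ids,
    intensity,
    ph,
    soc,
    traits: dict[str, np.ndarray],
    regimes,
    noise_sd: float,
    rng,
) -> pd.DataFrame:
    """Back-derive raw measurement columns from planted replicate traits."""
    ph = np.asarray(ph, dtype=float)
    soc = np.asarray(soc, dtype=float)
    dna_c = traits["dna_c"]
    dna13 = traits["turnover"] * dna_c
    co213 = dna13 * (1.0 - traits["cue"]) / traits["cue"]
    basal = traits["qco2"] * dna_c
    activity = traits["enzyme_investment"] * dna_c

    n = len(ph)
    moisture = np.clip(85.0 - 8.0 * ph + rng.normal(0, 30 * noise_sd, n), 2.0, 95.0)
    clay = np.clip(rng.uniform(5, 40, n) + rng.normal(0, 10 * noise_sd, n), 0.5, 70.0)
    cn = np.clip(11.0 + rng.normal(0, 8 * noise_sd, n), 6.0, 25.0)
    loi = np.clip(
        (1.9 * soc + 0.8) * np.exp(rng.normal(0, 0.3 * noise_sd, n)), 0.1, 100.0
    )

    frame = pd.DataFrame(
        {
            "site_id": site_ids,
            "pair_id": pair_ids,
            "intensity": intensity,
            "ph": ph,
            "moisture_pct": moisture,
            "clay_pct": clay,
            "c_pct": soc,
            "n_pct": soc / cn,
            "loi_pct": loi,
            "dna_c": dna_c,
            "dna_13c_excess": dna13,
            "co2_13c_excess": co213,
            "basal_resp": basal,
            "enzyme_activity": activity,
            "regime": regimes,
        }
    )
    for trait in _TRAITS:
        frame[f"true_{trait}"] = traits[trait]
    return frame


def generate_survey(config: SurveyConfig) -> pd.DataFrame:
    """Generate a landscape survey with a planted pH regime switch.

    Site pH is uniform over ``ph_range``; replicate pH adds a small
    within-site jitter. Each replicate's SOC is drawn from its pH
    regime's distribution (acidic sites carry more carbon) and its
    traits follow the regime's trait–SOC model plus noise; raw
    measurement columns are back-derived so the physiology module
    recovers the planted (noised) traits exactly. Deterministic for a
    fixed config (identical seed ⇒ bit-identical table).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites * config.reps_per_site

    site_ph = rng.uniform(*config.ph_range, size=config.n_sites)
    ph = np.repeat(site_ph, config.reps_per_site) + rng.normal(0, PH_JITTER_SD, n)
    ph = np.clip(ph, config.ph_range[0], config.ph_range[1])
    regimes = _regime(ph, config.ph_break)

    # SOC: one site-level draw per regime, small replicate-level spread
    soc = np.empty(n)
    site_idx = np.repeat(np.arange(config.n_sites), config.reps_per_site)
    site_reg = _regime(site_ph, config.ph_break)
    site_soc = np.empty(config.n_sites)
    for reg, pars in _SOC_SAMPLER.items():
        mask = site_reg == reg
        draws = np.exp(
            rng.normal(np.log(pars["median"]), pars["sigma"], size=mask.sum())
        )
        site_soc[mask] = np.clip(draws, pars["lo"], pars["hi"])
    soc = site_soc[site_idx] * np.exp(rng.normal(0, 0.2 * config.noise_sd, n))

    planted = _planted_traits(soc, regimes, config.trait_models)
    traits = _add_trait_noise(planted, config.noise_sd, rng)

    site_ids = np.repeat(
        np.array([f"S{i + 1:03d}" for i in range(config.n_sites)]), config.reps_per_site
    )
    frame = _assemble_rows(
        site_ids=site_ids,
        pair_ids=np.repeat("", n),
        intensity=np.repeat("none", n),
        ph=ph,
        soc=soc,
        traits=traits,
        regimes=regimes,
        noise_sd=config.noise_sd,
        rng=rng,
    )
    frame.insert(1, "replicate", np.tile(np.arange(1, config.reps_per_site + 1), config.n_sites))
    return frame


def _place_pair_ph(pair_type: int, config: ContrastConfig, rng) -> tuple[float, float]:
    lo, hi = config.ph_range
    b = config.ph_break
    margin = 0.15
    if pair_type == 1:
        low = rng.uniform(b + margin, hi)
        high = np.clip(low + rng.uniform(-0.3, 0.8), b + margin, hi)
    elif pair_type == 2:
        low = rng.uniform(lo + 0.05, b - margin)
        high = rng.uniform(b + margin, min(b + 1.6, hi))
    else:
        low = rng.uniform(lo + 0.05, b - margin)
        high = np.clip(low + rng.uniform(-0.2, 0.5), lo + 0.05, b - margin)
    return float(low), float(high)


def generate_contrasts(config: ContrastConfig) -> pd.DataFrame:
    """Generate paired low/high-intensity contrasts with planted effects.

    Each pair contributes two sites (one per intensity) with
    ``reps_per_site`` replicates. Pair pH placement obeys the planted
    type; the high-intensity member's traits are the low member's
    planted traits scaled by ``effect_size`` in the configured
    direction, then noised and back-derived into raw measurements.
    Returns a survey-schema frame with ``pair_id``, ``intensity`` and a
    ``true_type`` column.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    pair_no = 0
    for pair_type, count in zip((1, 2, 3), config.n_pairs_per_type):
        dirs = config.effect_directions.get(pair_type, {})
        for _ in range(count):
            pair_no += 1
            pid = f"P{pair_no:02d}"
            ph_low, ph_high = _place_pair_ph(pair_type, config, rng)
            reps = config.reps_per_site

            # low-intensity member: traits from its own regime model
            reg_low = str(_regime([ph_low], config.ph_break)[0])
            pars = _SOC_SAMPLER[reg_low]
            soc_low = float(
                np.clip(
                    np.exp(rng.normal(np.log(pars["median"]), pars["sigma"])),
                    pars["lo"],
                    pars["hi"],
                )
            )
            # planted SOC effect on the high member
            c_dir = dirs.get("c_pct", "none")
            c_fac = {"increase": config.effect_size, "decrease": 1 / config.effect_size,
                     "none": 1.0}[c_dir]
            soc_high = soc_low * c_fac

            for intensity, ph_site, soc_site in (
                ("low", ph_low, soc_low),
                ("high", ph_high, soc_high),
            ):
                ph_rep = np.clip(
                    ph_site + rng.normal(0, PH_JITTER_SD, reps), *config.ph_range
                )
                soc_rep = np.full(reps, soc_site) * np.exp(
                    rng.normal(0, 0.2 * config.noise_sd, reps)
                )
                reg_rep = np.repeat(reg_low, reps)  # traits anchored to low regime
                planted = _planted_traits(soc_rep, reg_rep, config.trait_models)
                if intensity == "high":
                    for trait in _TRAITS + ("dna_c",):
                        d = dirs.get(trait, "none")
                        if d == "increase":
                            planted[trait] = planted[trait] * config.effect_size
                        elif d == "decrease":
                            planted[trait] = planted[trait] / config.effect_size
                    planted["cue"] = np.clip(planted["cue"], 1e-4, 1 - 1e-4)
                    planted["turnover"] = np.clip(planted["turnover"], 1e-3, 1 - 1e-3)
                traits = _add_trait_noise(planted, config.noise_sd, rng)
                frame = _assemble_rows(
                    site_ids=np.repeat(f"{pid}{'L' if intensity == 'low' else 'H'}", reps),
                    pair_ids=np.repeat(pid, reps),
                    intensity=np.repeat(intensity, reps),
                    ph=ph_rep,
                    soc=soc_rep,
                    traits=traits,
                    regimes=_regime(ph_rep, config.ph_break),
                    noise_sd=config.noise_sd,
                    rng=rng,
                )
                frame.insert(1, "replicate", np.arange(1, reps + 1))
                frame["true_type"] = pair_type
                frames.append(frame)
    if not frames:
        cols = SURVEY_COLUMNS + ["replicate", "regime", "true_type"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


_CLASS_POOL = [
    "Metabolism",
    "Genetic information processing",
    "Environmental information processing",
    "Cellular processes",
    "Unclassified",
]


def generate_feature_table(config: FeatureTableConfig) -> FeatureTable:
    """Generate a two-group feature table with planted indicators.

    Background features are exchangeable between groups (same presence
    probability and abundance law); the first ``n_planted_indicators``
    features per group have presence ``indicator_presence_in`` and a
    ``indicator_abundance_fold``-fold abundance boost in their group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features
    n_per = config.n_samples_per_group
    groups = pd.Series(
        ["low"] * n_per + ["high"] * n_per,
        index=[f"L{i + 1}" for i in range(n_per)] + [f"H{i + 1}" for i in range(n_per)],
        name="group",
    )
    feature_ids = [f"F{i + 1:04d}" for i in range(n_feat)]

    abund = rng.lognormal(config.abundance_mu, config.abundance_sigma, (n_feat, 2 * n_per))
    present = rng.random((n_feat, 2 * n_per)) < config.presence_prob_background

    planted_rows = []
    k = config.n_planted_indicators
    for g_idx, gname in enumerate(("low", "high")):
        cols = slice(0, n_per) if gname == "low" else slice(n_per, 2 * n_per)
        other = slice(n_per, 2 * n_per) if gname == "low" else slice(0, n_per)
        rows = range(g_idx * k, (g_idx + 1) * k)
        for r in rows:
            present[r, cols] = rng.random(n_per) < config.indicator_presence_in
            present[r, other] = rng.random(n_per) < config.indicator_presence_out
            abund[r, cols] *= config.indicator_abundance_fold
            planted_rows.append({"feature_id": feature_ids[r], "group": gname})

    matrix = pd.DataFrame(
        abund * present, index=pd.Index(feature_ids, name="feature_id"),
        columns=groups.index,
    )
    class_map = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "level1_class": rng.choice(_CLASS_POOL, size=n_feat),
        }
    )
    planted = pd.DataFrame(planted_rows, columns=["feature_id", "group"])
    return FeatureTable(matrix, groups, class_map, planted)


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_survey(frame: pd.DataFrame, path, *, seed: int | None = None) -> None:
    """Write a survey as tab-delimited text with the documented header.

    Only the documented schema columns are written; generator
    ground-truth columns stay in memory. The seed is recorded as a
    comment line.
    """
    with open(path, "w") as fh:
        fh.write("# soilcue survey v1\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        frame.loc[:, SURVEY_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_survey(path) -> pd.DataFrame:
    """Read a tab-delimited survey table (``#`` lines are comments)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_feature_table(table: FeatureTable, path) -> None:
    """Write features × samples as tab-delimited text with a group row."""
    with open(path, "w") as fh:
        fh.write("# soilcue feature table v1\n")
        fh.write("group\t" + "\t".join(table.groups.astype(str)) + "\n")
        table.abundances.to_csv(fh, sep="\t")


def read_feature_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a feature table written by :func:`write_feature_table`."""
    with open(path) as fh:
        group_line = None
        skip = 0
        for line in fh:
            skip += 1
            if line.startswith("#"):
                continue
            if line.startswith("group\t"):
                group_line = line.rstrip("\n").split("\t")[1:]
                break
            raise ValueError("expected a 'group' header row")
    matrix = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    groups = pd.Series(group_line, index=matrix.columns, name="group")
    return matrix, groups
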