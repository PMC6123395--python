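"""End-to-end pipeline: traits → threshold → models → contrasts → IndVal.

A pipeline run is driven by a plain-dict (YAML-friendly) configuration
with one top-level ``seed``; every stage that needs randomness derives
its own seed deterministically from it, so re-running an identical
config reproduces every output byte for byte. Each stage writes its
table into the run directory as delimited text and the run ends with a
``manifest.json`` recording the config hash, seed and per-stage row
counts. A stage failure aborts with a stage-named error; tables
already written stay on disk.

Config keys (all optional except where noted)::

    seed: 0                       # master seed
    survey:                       # exactly one of path | generate
      path: survey.tsv
      generate: {n_sites: 56, reps_per_site: 3, ph_break: 6.2, ...}
    contrasts:
      pairs_fixture: true         # use the packaged 21-pair table
      generate: {n_pairs_per_type: [11, 6, 4], ...}
    features:
      path: features.tsv
      generate: {n_features: 200, n_samples_per_group: 3, ...}
    threshold: {window_width: 1.4, step: 0.1, ...}
    models: {criterion: aicc}
    indval: {n_permutations: 1000, statistic: max}
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from soilcue import contrasts as contrasts_mod
from soilcue import synthetic
from soilcue.indicators import aggregate_by_class, indval_significance
from soilcue.models import segment_model_table
from soilcue.partitioning import ThresholdConfig, slope_failure_threshold
from soilcue.physiology import derive_traits

__all__ = ["PipelineError", "run_pipeline", "load_config"]

#: fold-change orientation recorded in the manifest: ratios are
#: high-intensity over low-intensity (effect of intensification)
FOLD_ORIENTATION = "high/low"


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    """Load a YAML pipeline config into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _dataclass_from(cfg: dict, cls, **overrides):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    merged = {**cfg, **overrides}
    if "n_pairs_per_type" in merged and isinstance(merged["n_pairs_per_type"], list):
        merged["n_pairs_per_type"] = tuple(merged["n_pairs_per_type"])
    if "ph_range" in merged and isinstance(merged["ph_range"], list):
        merged["ph_range"] = tuple(merged["ph_range"])
    return cls(**merged)


def _one_of(cfg: dict, stage: str, keys: tuple) -> str:
    given = [k for k in keys if cfg.get(k)]
    if len(given) != 1:
        raise PipelineError(
            stage, f"exactly one of {keys} must be set; got {given or 'none'}"
        )
    return given[0]


def _write(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, sep="\t", index=False)
    return len(frame)


def run_pipeline(config: dict, outdir) -> dict:
    """Run every configured stage; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    canonical = yaml.safe_dump(config, sort_keys=True)
    manifest: dict = {
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "fold_change_orientation": FOLD_ORIENTATION,
        "rows": {},
        "results": {},
    }

    # ---- survey ----
    survey = None
    if "survey" in config:
        stage = "survey"
        try:
            which = _one_of(config["survey"], stage, ("path", "generate"))
            if which == "path":
                survey = synthetic.read_survey(config["survey"]["path"])
            else:
                gen = dict(config["survey"]["generate"])
                gen.setdefault("seed", seed)
                survey = synthetic.generate_survey(
                    _dataclass_from(gen, synthetic.SurveyConfig)
                )
                synthetic.write_survey(survey, outdir / "survey.tsv", seed=gen["seed"])
            manifest["rows"][stage] = len(survey)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- contrast survey (replicate-level, generated) ----
    contrast_survey = None
    pairs_table = None
    if "contrasts" in config:
        stage = "contrasts-input"
        try:
            which = _one_of(
                config["contrasts"], stage, ("path", "generate", "pairs_fixture")
            )
            if which == "path":
                contrast_survey = synthetic.read_survey(config["contrasts"]["path"])
            elif which == "generate":
                gen = dict(config["contrasts"]["generate"])
                gen.setdefault("seed", seed + 1)
                contrast_survey = synthetic.generate_contrasts(
                    _dataclass_from(gen, synthetic.ContrastConfig)
                )
                synthetic.write_survey(
                    contrast_survey, outdir / "contrast_survey.tsv", seed=gen["seed"]
                )
            else:
                pairs_table = contrasts_mod.load_contrast_table()
            if contrast_survey is not None:
                manifest["rows"][stage] = len(contrast_survey)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- traits ----
    traits = None
    if survey is not None:
        stage = "traits"
        try:
            traits = derive_traits(survey)
            manifest["rows"][stage] = _write(traits, outdir / "traits.tsv")
            if len(traits) != len(survey):
                raise ValueError("row count changed during trait derivation")
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- threshold ----
    threshold_value = float(config.get("threshold", {}).get("fixed", float("nan")))
    if traits is not None:
        stage = "threshold"
        try:
            tcfg_dict = {
                k: v
                for k, v in config.get("threshold", {}).items()
                if k != "fixed"
            }
            tcfg = _dataclass_from(tcfg_dict, ThresholdConfig)
            sub = traits.dropna(subset=["cue"])
            result = slope_failure_threshold(
                sub["ph"].to_numpy(), sub["c_pct"].to_numpy(), sub["cue"].to_numpy(), tcfg
            )
            result.profile.to_csv(outdir / "threshold_profile.tsv", sep="\t", index=False)
            manifest["rows"][stage] = len(result.profile)
            manifest["results"]["threshold"] = {
                "detected": result.detected,
                "threshold": None if not result.detected else result.threshold,
            }
            if result.detected and not (threshold_value == threshold_value):
                threshold_value = result.threshold
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
    if threshold_value != threshold_value:  # still NaN
        threshold_value = contrasts_mod.DEFAULT_PH_THRESHOLD

    # ---- segmented models ----
    if traits is not None:
        stage = "models"
        try:
            criterion = config.get("models", {}).get("criterion", "aicc")
            table = segment_model_table(traits, threshold_value, criterion=criterion)
            manifest["rows"][stage] = _write(table, outdir / "models.tsv")
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- contrasts ----
    if contrast_survey is not None or pairs_table is not None:
        stage = "contrasts"
        try:
            if contrast_survey is not None:
                ctraits = derive_traits(contrast_survey)
                summary = contrasts_mod.summarize_contrasts(ctraits, threshold_value)
            else:
                summary = contrasts_mod.classify_pairs(pairs_table, threshold_value)
            manifest["rows"][stage] = _write(summary, outdir / "contrast_summary.tsv")
            counts = summary["type"].value_counts().to_dict()
            manifest["results"]["contrast_type_counts"] = {
                str(k): int(v) for k, v in sorted(counts.items())
            }
            by_type = contrasts_mod.summarize_by_type(summary)
            if not by_type.empty:
                _write(by_type, outdir / "contrast_by_type.tsv")
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- indicators ----
    if "features" in config:
        stage = "indval"
        try:
            which = _one_of(config["features"], stage, ("path", "generate"))
            if which == "path":
                matrix, fgroups = synthetic.read_feature_table(config["features"]["path"])
                class_map = None
            else:
                gen = dict(config["features"]["generate"])
                gen.setdefault("seed", seed + 2)
                table = synthetic.generate_feature_table(
                    _dataclass_from(gen, synthetic.FeatureTableConfig)
                )
                matrix, fgroups, class_map = table.abundances, table.groups, table.class_map
                synthetic.write_feature_table(table, outdir / "features.tsv")
            icfg = config.get("indval", {})
            results = indval_significance(
                matrix,
                fgroups,
                n_permutations=int(icfg.get("n_permutations", 1000)),
                seed=int(icfg.get("seed", seed + 3)),
                statistic=icfg.get("statistic", "max"),
            )
            manifest["rows"][stage] = len(results)
            results.reset_index(names="feature_id").to_csv(
                outdir / "indval.tsv", sep="\t", index=False
            )
            manifest["results"]["n_significant_features"] = int(
                (results["p_value"] <= float(icfg.get("alpha", 0.05))).sum()
            )
            if class_map is not None:
                classes = aggregate_by_class(
                    results, class_map, matrix, fgroups,
                    alpha=float(icfg.get("alpha", 0.05)),
                )
                _write(classes, outdir / "indval_classes.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
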