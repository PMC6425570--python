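"""Pipeline orchestration: simulate -> classify -> fit -> validate -> report.

Each stage reads and writes delimited text under a single output
directory, logs record-level fallbacks, and a run manifest (config hash,
seed, input digests) makes reruns auditable: identical manifests imply
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .abortion_data import AbortionDatum, classify_abortion_datum
from .intention_data import BirthRecord, IntentionDatum, classify_intention_datum
from .observations import (
    ClassifiedObservation,
    observations_to_frame,
    observations_from_frame,
)
from .inference import build_model, fit, validate_holdout
from .synthetic import (
    SyntheticWorldConfig,
    ObservationProcessConfig,
    generate_world,
    generate_observations,
)

logger = logging.getLogger("pregtrends")

__all__ = ["RunManifest", "run_pipeline", "classify_all", "load_config"]

_OPTIONAL_FLOATS = (
    "acknowledged_completeness", "sampling_variance",
    "aicm_complications_treated", "aicm_total_complications",
    "aicm_multiplier", "aicm_legal_abortions",
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    input_digests: dict
    package_version: str
    created: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    """numpy scalars -> python scalars for json.dumps."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# Datum frame round-trips


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    return value


def abortion_data_from_frame(frame: pd.DataFrame) -> list[AbortionDatum]:
    out = []
    fields = set(AbortionDatum.__dataclass_fields__)
    for row in frame.to_dict("records"):
        d = {k: v for k, v in row.items() if k in fields}
        for key in _OPTIONAL_FLOATS + ("below_survey_estimate", "region", "datum_id"):
            if key in d:
                d[key] = _opt(d[key])
        out.append(AbortionDatum(**d))
    return out


def intention_data_from_frame(frame: pd.DataFrame) -> list[IntentionDatum]:
    out = []
    fields = set(IntentionDatum.__dataclass_fields__)
    for row in frame.to_dict("records"):
        d = {k: v for k, v in row.items() if k in fields}
        for key in ("sampling_error", "lmup_planned", "lmup_ambivalent",
                    "lmup_unwanted", "percent_marital_intended", "region",
                    "datum_id"):
            if key in d:
                d[key] = _opt(d[key])
        records = d.get("birth_records")
        if isinstance(records, str) and records:
            d["birth_records"] = [
                BirthRecord(**r) for r in json.loads(records)
            ]
        elif isinstance(records, float) and np.isnan(records):
            d["birth_records"] = None
        out.append(IntentionDatum(**d))
    return out


def _serialize_records(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    if "birth_records" in frame.columns:
        frame["birth_records"] = frame["birth_records"].map(
            lambda v: json.dumps([asdict(r) for r in v], default=_jsonable)
            if isinstance(v, (list, tuple)) else ""
        )
    return frame


# ---------------------------------------------------------------------------
# Classification stage


def classify_all(
    abortion_data: list[AbortionDatum],
    intention_data: list[IntentionDatum],
    regions: dict,
    mean_sampling_error: Optional[float] = None,
) -> tuple[list[ClassifiedObservation], pd.DataFrame]:
    """Classify every datum; returns observations plus a loss-free audit
    trail (one row per input datum with its path through the tree).

    A region has an under-reporting estimate when some country in it pairs
    a survey of women with an official statistic that classifies as a
    point estimate (the coincidence that identifies the inflation factor).
    """
    # first pass: classify official statistics to find reliable registries
    region_flag: dict[str, bool] = {}
    official_obs: dict[int, ClassifiedObservation] = {}
    survey_countries = {
        (d.country) for d in abortion_data
        if d.source == "published_study" and d.method == "womens_reports"
        and not d.special_population
    }
    for i, d in enumerate(abortion_data):
        if d.source == "official_statistic" and not d.special_population:
            obs = classify_abortion_datum(d)
            official_obs[i] = obs
            region = d.region or regions.get(d.country)
            if obs.bound == "point" and d.country in survey_countries:
                region_flag[region] = True

    if mean_sampling_error is None:
        known = [d.sampling_error for d in intention_data
                 if d.sampling_error is not None]
        mean_sampling_error = float(np.mean(known)) if known else 2.0
        if not known:
            logger.warning("no intention datum reports a sampling error; "
                           "using the config default 2.0")

    observations: list[ClassifiedObservation] = []
    audit_rows = []
    for i, d in enumerate(abortion_data):
        region = d.region or regions.get(d.country)
        if i in official_obs:
            obs = official_obs[i]
        else:
            obs = classify_abortion_datum(
                d, region_has_underreporting_estimate=region_flag.get(region, False)
            )
        obs.region = region
        observations.append(obs)
        audit_rows.append({
            "datum_id": d.datum_id, "kind": "abortion", "country": d.country,
            "period": d.period, "outcome": "excluded" if obs.excluded else obs.bound,
            "path": obs.audit,
        })
    for d in intention_data:
        region = d.region or regions.get(d.country)
        obs_list = classify_intention_datum(d, mean_sampling_error)
        for obs in obs_list:
            obs.region = region
        observations.extend(obs_list)
        audit_rows.append({
            "datum_id": d.datum_id, "kind": "intention", "country": d.country,
            "period": d.period,
            "outcome": "excluded" if obs_list[0].excluded else
            "+".join(o.bound for o in obs_list),
            "path": " | ".join(o.audit for o in obs_list),
        })
    return observations, pd.DataFrame(audit_rows)


# ---------------------------------------------------------------------------
# Full pipeline


def run_pipeline(config, output_dir, seed: Optional[int] = None) -> Path:
    """Execute the configured stages and write all outputs.

    ``config`` is a YAML path or a dict.  Returns the output directory.
    """
    from . import __version__

    config_path = None
    if not isinstance(config, dict):
        config_path = Path(config)
        config = load_config(config_path)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", ["simulate", "classify", "fit", "report"])

    stage = "setup"
    try:
        digests = {}
        # --- simulate ------------------------------------------------------
        stage = "simulate"
        world_cfg = SyntheticWorldConfig(seed=seed, **cfg.get("world", {}))
        obs_cfg = ObservationProcessConfig(
            seed=seed + 1, **cfg.get("observation_process", {})
        )
        truth = generate_world(world_cfg)
        ab_frame, int_frame = generate_observations(truth, obs_cfg)
        if "simulate" in stages:
            truth.exposure.to_frame().to_csv(out / "exposure.csv", index=False)
            truth.exposure.births_frame().to_csv(out / "births.csv", index=False)
            truth.covariates.to_csv(out / "covariates.csv", index=False)
            _serialize_records(ab_frame).to_csv(out / "abortion_data.csv", index=False)
            _serialize_records(int_frame).to_csv(out / "intention_data.csv", index=False)
            truth_ind = truth.indicator_truth()
            rows = []
            for ind, arr in truth_ind.items():
                for ci, c in enumerate(truth.exposure.countries):
                    for ti, p in enumerate(truth.exposure.periods):
                        rows.append((c, p, ind, arr[ci, ti]))
            pd.DataFrame(rows, columns=["country", "period_start", "indicator",
                                        "truth"]).to_csv(out / "truth.csv", index=False)
            for name in ("exposure", "births", "covariates", "abortion_data",
                         "intention_data"):
                digests[name] = _digest(out / f"{name}.csv")

        # --- classify -------------------------------------------------------
        stage = "classify"
        observations, audit = classify_all(
            abortion_data_from_frame(ab_frame),
            intention_data_from_frame(_serialize_records(int_frame)),
            regions=truth.regions,
        )
        if "classify" in stages:
            observations_to_frame(observations).to_csv(
                out / "observations.csv", index=False
            )
            audit.to_csv(out / "audit.csv", index=False)

        model_cfg_dict = dict(cfg.get("model", {}))
        sampler = dict(model_cfg_dict.pop("sampler", {}))
        sampler.setdefault("seed", seed)
        model_config = truth.model_config(
            covariates=model_cfg_dict.pop("covariates", None),
            sampler=sampler, **model_cfg_dict,
        )

        posterior = None
        if "fit" in stages:
            stage = "fit"
            model = build_model(
                observations, truth.exposure, model_config, truth.covariates
            )
            posterior = fit(model)
            (out / "diagnostics.json").write_text(
                json.dumps(posterior.diagnostics, indent=2, sort_keys=True,
                           default=_jsonable)
            )

        if "validate" in stages:
            stage = "validate"
            res = validate_holdout(
                observations, truth.exposure, model_config,
                scheme=cfg.get("validation", {}).get("scheme", "random_subset"),
                fraction_or_country=cfg.get("validation", {}).get(
                    "fraction_or_country", 0.2),
                seed=seed, covariates=truth.covariates,
            )
            res["metrics"].to_csv(out / "validation_metrics.csv", index=False)
            (out / "validation_summary.json").write_text(
                json.dumps(res["summary"], indent=2, sort_keys=True,
                           default=_jsonable)
            )

        if "report" in stages and posterior is not None:
            stage = "report"
            frames = []
            for level in ("country", "region", "global"):
                summary = posterior.indicator_summary(level)
                summary.insert(0, "level", level)
                frames.append(summary)
            report = pd.concat(frames, ignore_index=True)
            if model_config.suppress_width_ratio is not None:
                report = _apply_suppression(report, posterior, model_config)
            report.to_csv(out / "indicators.csv", index=False)

        stage = "manifest"
        manifest = RunManifest(
            config_hash=hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            seed=seed,
            input_digests=digests,
            package_version=__version__,
            created=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        )
        (out / "manifest.json").write_text(manifest.to_json())
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _apply_suppression(report, posterior, config):
    """Suppress country rows whose posterior is essentially the prior.

    The rule compares each country's 95% interval width for the abortion
    rate against a data-free (prior-only) fit of the same model.
    """
    prior_config = config.copy()
    prior_config.covariates = []
    prior_model = build_model([], posterior.model.exposure, prior_config, None)
    prior_post = fit(prior_model)
    prior_sum = prior_post.indicator_summary("country")
    key = ["unit", "period_start", "indicator"]
    merged = report.merge(
        prior_sum[key + ["lower95", "upper95"]], on=key, how="left",
        suffixes=("", "_prior"),
    )
    width = merged["upper95"] - merged["lower95"]
    width_prior = merged["upper95_prior"] - merged["lower95_prior"]
    ratio = width / width_prior.replace(0, np.nan)
    drop = (
        (merged["level"] == "country")
        & (ratio > config.suppress_width_ratio)
    )
    suppressed = merged.loc[~drop.fillna(False), report.columns]
    n = int(drop.fillna(False).sum())
    if n:
        logger.info("suppressed %d country rows with near-prior uncertainty", n)
    return suppressed
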