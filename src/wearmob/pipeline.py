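"""One-command orchestration: simulate/load -> process -> annotate -> infer.

Every run writes its output tables plus ``manifest.json`` recording the
configuration hash, seed, per-stage row counts, exclusion tallies and file
checksums, so that a run is fully auditable and (config, seed) determines
every output byte. Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .design import annotate, builtin_calendars, load_calendars_yaml
from .inference import (
    ELIGIBILITY_FLAGS,
    describe_cohort,
    fit_mixed,
    level_contrasts,
    level_means,
    weekly_series,
)
from .sensor import process
from .synthetic import simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["StageError", "RunManifest", "run_pipeline"]

OUTCOMES = ("fraction_home", "total_steps")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    row_counts: dict[str, int]
    tallies: dict[str, int]
    files: dict[str, str]  # name -> sha256

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write every output table under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row_counts: dict[str, int] = {}
    files: dict[str, str] = {}
    tallies: dict[str, int] = {}

    # --- stage: simulate or load -------------------------------------------
    try:
        if config.simulate is not None:
            sim = config.simulate.model_copy(update={"seed": config.seed})
            cohort = simulate_cohort(sim)
            for p in cohort.write(out):
                files[p.name] = _sha256(p)
            intervals, participants = cohort.intervals, cohort.participants
            weather, dds = cohort.weather, cohort.dds_days
        else:
            intervals = pd.read_csv(config.intervals_csv)
            participants = pd.read_csv(config.participants_csv)
            weather = None  # weather belongs to the study_design stage
            dds = (
                pd.read_csv(config.dds_csv)
                if config.dds_csv is not None
                else pd.DataFrame(columns=["site", "date"])
            )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("synthetic_cohort" if config.simulate is not None else "load", exc)
    row_counts["intervals"] = len(intervals)

    # --- stage: sensor processing ------------------------------------------
    try:
        result = process(intervals, participants, dds=dds, radius_m=config.radius_m)
    except Exception as exc:
        raise StageError("sensor_processing", exc)
    daily = result.daily_metrics
    tallies.update(result.tallies)
    row_counts["daily_metrics"] = len(daily)
    daily_path = out / "daily_metrics.csv"
    daily.assign(date=daily["date"].dt.strftime("%Y-%m-%d")).to_csv(daily_path, index=False)
    files[daily_path.name] = _sha256(daily_path)

    # --- stage: study design -----------------------------------------------
    try:
        if weather is None:
            weather = pd.read_csv(config.weather_csv)
        calendars = (
            load_calendars_yaml(config.calendar_yaml)
            if config.calendar_yaml is not None
            else builtin_calendars()
        )
        analysis = annotate(
            daily,
            participants,
            weather,
            calendars=calendars,
            harmonic_period_days=config.harmonic_period_days,
            weather_interp_limit_days=config.weather_interp_limit_days,
        )
    except Exception as exc:
        raise StageError("study_design", exc)
    row_counts["analysis_table"] = len(analysis)
    tallies["weather_drops"] = row_counts["daily_metrics"] - len(analysis)
    a_path = out / "analysis_table.csv"
    analysis.assign(date=analysis["date"].dt.strftime("%Y-%m-%d")).to_csv(a_path, index=False)
    files[a_path.name] = _sha256(a_path)

    # --- stage: inference ---------------------------------------------------
    try:
        observed, stratified, model_rows, contrast_rows = [], [], [], []
        has_flags = all(f in participants.columns for f in ELIGIBILITY_FLAGS)
        if has_flags:
            sev = participants.set_index("participant_id")[ELIGIBILITY_FLAGS].sum(axis=1)
            analysis = analysis.assign(
                severity=analysis["participant_id"].map(sev.clip(upper=3))
            )
        for site in sorted(analysis["site"].unique()):
            sub = analysis[analysis["site"] == site]
            current = sub[sub["year_2020"] == 1]
            for outcome in OUTCOMES:
                observed.append(level_means(current, outcome, site=site))
                if has_flags:
                    strat = level_means(current, outcome, site=site, stratum_col="severity")
                    if len(strat):
                        strat["site"] = site
                        stratified.append(strat)
                fit = fit_mixed(sub, outcome)
                t = fit.terms.copy()
                t.insert(0, "site", site)
                t.insert(1, "outcome", outcome)
                t["group_var"] = fit.group_var
                t["resid_var"] = fit.resid_var
                t["n_obs"] = fit.n_obs
                t["n_participants"] = fit.n_participants
                model_rows.append(t)
                c = level_contrasts(fit, adjustment=config.contrast_adjustment)
                c.insert(0, "site", site)
                contrast_rows.append(c)
        weekly = weekly_series(analysis)
        outputs = {
            "table_observed_levels.csv": pd.concat(observed, ignore_index=True),
            "cohort_demographics.csv": describe_cohort(participants),
            "table_model_coefficients.csv": pd.concat(model_rows, ignore_index=True),
            "contrasts.csv": pd.concat(contrast_rows, ignore_index=True),
            "weekly_series.csv": weekly,
        }
        if stratified:
            outputs["table_observed_by_severity.csv"] = pd.concat(
                stratified, ignore_index=True
            )
        for name, df in outputs.items():
            p = out / name
            df.to_csv(p, index=False)
            files[name] = _sha256(p)
    except Exception as exc:
        raise StageError("inference", exc)

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            config.model_dump_json(exclude={"out_dir"}).encode()
        ).hexdigest(),
        seed=config.seed,
        version=__version__,
        row_counts=row_counts,
        tallies=tallies,
        files=files,
    )
    manifest.write(out / "manifest.json")
    logger.info("pipeline complete; %d files in %s", len(files), out)
    return manifest
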