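"""End-to-end study runs: simulate/read → condition → detect → agree.

One run equals one study. Per-trial variables are cached as canonical
delimited tables so the agreement stage can be re-run without repeating
detection; every output carries a provenance block (config, seed,
version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import build_tables
from .core import TrialRecording
from .events import EventConfig, NoCountermovementError, detect_and_extract
from .io import (read_canonical, recordings_to_frame, variables_to_frame,
                 write_variables)
from .preprocess import (CalibrationSpec, ConditioningConfig,
                         UnrecoverableTrajectoryError, condition)
from .synthetic import (JumpPopulation, NoiseModel, SimulatedStudy,
                        StudyDesign, simulate_study)

log = logging.getLogger("cmjkin")


@dataclass
class RunConfig:
    """Configuration of one study run (YAML-loadable).

    Exactly one input source: either ``input_path`` (canonical long
    table) or ``simulate=True`` with design/population/noise settings.
    """

    simulate: bool = True
    input_path: Optional[str] = None
    design: StudyDesign = field(default_factory=StudyDesign)
    population: JumpPopulation = field(default_factory=JumpPopulation)
    noise_2d_rater_a: Optional[NoiseModel] = None
    noise_2d_rater_b: Optional[NoiseModel] = None
    noise_3d: Optional[NoiseModel] = None
    conditioning: ConditioningConfig = field(
        default_factory=ConditioningConfig)
    events: EventConfig = field(default_factory=EventConfig)
    calibration: Optional[CalibrationSpec] = None
    average_trials: bool = True
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate == (self.input_path is not None):
            raise ValueError(
                "exactly one input source: simulate or input_path")
        self.design = dataclasses.replace(self.design, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (("design", StudyDesign),
                         ("population", JumpPopulation),
                         ("conditioning", ConditioningConfig),
                         ("events", EventConfig),
                         ("calibration", CalibrationSpec),
                         ("noise_2d_rater_a", NoiseModel),
                         ("noise_2d_rater_b", NoiseModel),
                         ("noise_3d", NoiseModel)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, tuple):
                return list(v)
            return v
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


@dataclass
class StudyReport:
    """All report tables of one run, with provenance."""

    variables: pd.DataFrame
    descriptives: pd.DataFrame
    reliability: pd.DataFrame          # video rater A vs B
    validity: dict[str, pd.DataFrame]  # per-rater vs mocap
    provenance: dict
    failures: list[dict] = field(default_factory=list)
    ground_truth: Optional[pd.DataFrame] = None


def extract_study_variables(recordings: list[TrialRecording],
                            cond_cfg: Optional[ConditioningConfig] = None,
                            event_cfg: Optional[EventConfig] = None,
                            calibration: Optional[CalibrationSpec] = None,
                            ) -> tuple[pd.DataFrame, list[dict]]:
    """Condition every trajectory and extract the five jump variables.

    Returns the long variables table and a list of per-trajectory
    failures (unrecoverable gaps, no detectable countermovement), each
    with trial-level context.
    """
    cond_cfg = cond_cfg or ConditioningConfig()
    event_cfg = event_cfg or EventConfig()
    records, failures = [], []
    for rec in recordings:
        for marker, traj in rec.trajectories.items():
            ctx = {"participant": rec.participant, "trial": rec.trial,
                   "source": rec.source, "rater": rec.rater or "",
                   "marker": marker}
            try:
                if traj.n_missing:
                    log.info("interpolating %d missing samples (%s)",
                             traj.n_missing, ctx)
                clean = condition(traj, cond_cfg, calibration)
                _, var = detect_and_extract(clean.z, clean.t, event_cfg)
            except (UnrecoverableTrajectoryError,
                    NoCountermovementError) as err:
                log.warning("trajectory excluded: %s (%s)", err, ctx)
                failures.append(ctx | {"error": str(err)})
                continue
            records.append(ctx | {"variables": var})
    return variables_to_frame(records), failures


def descriptives(variables: pd.DataFrame,
                 by: tuple[str, ...] = ("marker", "source", "rater"),
                 ) -> pd.DataFrame:
    """Mean ± SD (n−1) of every variable per group."""
    value_cols = [c for c in ("dt_ecc", "dt_PP", "dt_take_off",
                              "h_Z_min", "h_Z_max")
                  if c in variables.columns]
    if variables.empty:
        raise ValueError("empty variables table")
    g = variables.groupby(list(by), dropna=False)[value_cols]
    out = g.agg(["mean", "std", "count"])
    out.columns = [f"{v}_{s}" for v, s in out.columns]
    # a singleton group has no n−1 SD; report 0 spread rather than NaN
    for c in out.columns:
        if c.endswith("_std"):
            out[c] = out[c].fillna(0.0)
    return out.reset_index()


def run_study(cfg: RunConfig) -> StudyReport:
    """Execute a full study and (optionally) persist all stage outputs."""
    ground_truth = None
    if cfg.simulate:
        study: SimulatedStudy = simulate_study(
            cfg.design, cfg.population, cfg.noise_2d_rater_a,
            cfg.noise_2d_rater_b, cfg.noise_3d, cfg.events)
        recordings = study.recordings
        ground_truth = study.ground_truth
    else:
        recordings = read_canonical(cfg.input_path)

    variables, failures = extract_study_variables(
        recordings, cfg.conditioning, cfg.events, cfg.calibration)
    if variables.empty:
        raise RuntimeError("no trajectory yielded variables")
    desc = descriptives(variables)

    labels = set(np.where(variables["source"].eq("mocap"), "mocap",
                          "video:" + variables["rater"].astype(str)))
    reliability = pd.DataFrame()
    validity: dict[str, pd.DataFrame] = {}
    if {"video:A", "video:B"} <= labels:
        reliability = build_tables(variables, "video:A", "video:B",
                                   average_trials=cfg.average_trials)
    for rater_label in sorted(lbl for lbl in labels if lbl != "mocap"):
        if "mocap" in labels:
            validity[rater_label] = build_tables(
                variables, "mocap", rater_label,
                average_trials=cfg.average_trials, with_pearson=True)

    cfg_dict = cfg.to_dict()
    provenance = {
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha1": hashlib.sha1(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "cmjkin_version": __version__,
        "n_recordings": len(recordings),
        "n_failures": len(failures),
    }
    report = StudyReport(variables=variables, descriptives=desc,
                         reliability=reliability, validity=validity,
                         provenance=provenance, failures=failures,
                         ground_truth=ground_truth)
    if cfg.outdir:
        _persist(report, recordings, cfg)
    return report


def _persist(report: StudyReport, recordings: list[TrialRecording],
             cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    recordings_to_frame(recordings).to_csv(out / "trajectories.csv",
                                           index=False, float_format="%.9g")
    write_variables(report.variables, out / "variables.csv", overwrite=True)
    report.descriptives.to_csv(out / "descriptives.csv", index=False)
    if not report.reliability.empty:
        report.reliability.to_csv(out / "reliability_interrater.csv",
                                  index=False)
    for label, tab in report.validity.items():
        safe = label.replace(":", "_")
        tab.to_csv(out / f"validity_{safe}.csv", index=False)
    if report.ground_truth is not None:
        report.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    if report.failures:
        pd.DataFrame(report.failures).to_csv(out / "excluded.csv",
                                             index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
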