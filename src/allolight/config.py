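"""Structured configuration and the multi-stage pipeline runner.

An :class:`AnalysisConfig` is validated before any stage runs (unknown keys
are rejected).  ``run_pipeline`` executes the declared stages in order on a
shared context, writes every output table to the configured directory, and
finishes with a machine-readable run manifest (package and library
versions, seed, parameter hash) so a rerun with the same manifest produces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as alio
from . import photometry as phot
from . import synthetic

logger = logging.getLogger(__name__)

__all__ = ["StageConfig", "AnalysisConfig", "load_config", "run_pipeline"]


class StageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    params: dict = Field(default_factory=dict)


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."
    stages: list[StageConfig] = Field(default_factory=list)


def load_config(path) -> AnalysisConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.model_validate(data)


def _stage_simulate_session(ctx, cfg: AnalysisConfig, **params):
    spec = synthetic.SessionSpec(seed=cfg.seed, **params)
    rec, trials, truth = synthetic.simulate_photometry_session(spec)
    ctx.update(recording=rec, trials=trials, truth=truth)
    out = Path(cfg.out_dir)
    alio.write_recording(out / "recording.csv", rec)
    alio.write_trials(out / "trials.csv", trials)
    alio.write_table(out / "ground_truth.csv",
                     pd.DataFrame([truth.params]), units="percent/seconds")


def _stage_read_recording(ctx, cfg, path, **_):
    ctx["recording"] = alio.read_recording(path)


def _stage_read_trials(ctx, cfg, path, **_):
    ctx["trials"] = alio.read_trials(path)


def _stage_preprocess(ctx, cfg, **params):
    ctx["recording"] = phot.preprocess(ctx["recording"], **params)


def _stage_dff(ctx, cfg: AnalysisConfig, **params):
    dff = phot.compute_dff(ctx["recording"], **params)
    ctx["dff"] = dff
    alio.write_table(Path(cfg.out_dir) / "dff.csv",
                     pd.DataFrame({"time_s": dff.time, "dff_pct": dff.dff}),
                     units="time_s=s, dff_pct=%")


def _stage_trial_metrics(ctx, cfg: AnalysisConfig, window=(-10.0, 60.0),
                         baseline_window=(-10.0, -1.0), quant_window=(0.0, 10.0)):
    aligned = phot.align_trials(ctx["dff"], ctx["trials"], window=tuple(window),
                                baseline_window=tuple(baseline_window))
    rows = []
    for i, (onset, trace) in enumerate(zip(aligned.onsets, aligned.traces)):
        m = phot.transient_metrics(aligned.rel_time, trace,
                                   quant_window=tuple(quant_window), compute_decay=True)
        rows.append((i, onset, m.peak, m.auc, m.off_decay))
    table = pd.DataFrame(rows, columns=["trial", "onset_s", "peak_pct", "auc",
                                        "off_decay_s"])
    ctx["trial_metrics"] = table
    alio.write_table(Path(cfg.out_dir) / "trial_metrics.csv", table,
                     units="onset_s=s, peak_pct=%, auc=%*s, off_decay_s=s")


def _stage_peaks(ctx, cfg: AnalysisConfig, **params):
    table = phot.detect_spontaneous_peaks(ctx["dff"], **params)
    ctx["peaks"] = table
    alio.write_table(Path(cfg.out_dir) / "peaks.csv", table,
                     units="time_s=s, peak_dff=%")


def _stage_tonic(ctx, cfg: AnalysisConfig, **params):
    baseline, auc = phot.tonic_baseline(ctx["dff"], **params)
    ctx["tonic_auc"] = auc
    alio.write_table(Path(cfg.out_dir) / "tonic_baseline.csv",
                     pd.DataFrame({"time_s": baseline.time,
                                   "baseline_pct": baseline.dff}),
                     units="time_s=s, baseline_pct=%")


_STAGES = {
    "simulate_session": _stage_simulate_session,
    "read_recording": _stage_read_recording,
    "read_trials": _stage_read_trials,
    "preprocess": _stage_preprocess,
    "dff": _stage_dff,
    "trial_metrics": _stage_trial_metrics,
    "peaks": _stage_peaks,
    "tonic": _stage_tonic,
}


def _param_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the configured stages in order and write a run manifest.

    Returns the shared context (recording, dff, tables...).  A stage
    failure aborts with the stage name and the error chained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    for stage in config.stages:
        if stage.name not in _STAGES:
            raise ValueError(f"unknown stage '{stage.name}' "
                             f"(known: {', '.join(sorted(_STAGES))})")
        logger.info("running stage %s", stage.name)
        try:
            _STAGES[stage.name](ctx, config, **stage.params)
        except Exception as exc:  # noqa: BLE001 - re-raise with provenance
            raise RuntimeError(f"stage '{stage.name}' failed: {exc}") from exc

    import scipy

    from . import __version__

    manifest = {
        "allolight": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "stages": [s.name for s in config.stages],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    ctx["manifest"] = manifest
    return ctx
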