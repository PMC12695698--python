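"""End-to-end orchestration with content-addressed stage caching.

Stages run in dependency order: simulate (or ingest of user-supplied CSVs),
filter_detections, filter_positions, classify, activity, kud, fit. Each
stage's cache key hashes the configuration slice it depends on plus the
content of its input files, so editing, say, the philopatry threshold
re-runs only classification and the model fit, while the expensive MCMC
stage survives upstream no-ops. The manifest records keys, row counts and
output hashes per stage; identical config + seed reproduce identical
manifests byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import telemetry
from .movement import activity_steps, aggregate_weekly
from .philopatry import PhilopatryConfig, build_presence, classify_all, sensitivity
from .solar import DielCalendar
from .space_use import KudConfig, build_model_table, weekly_space_use
from .syndrome import (McmcSettings, ModelSpec, build_design, diagnostics,
                       draws_frame, gibbs_fit, summarize)
from .synthetic import SimConfig, write_simulated
from .telemetry import write_csv

log = logging.getLogger(__name__)

STAGES = ["simulate", "filter_detections", "filter_positions",
          "classify", "activity", "kud", "fit"]


def demo_sim_config(seed: int = 0) -> SimConfig:
    """Small raw-level cohort for end-to-end runs: one season, a dozen
    animals, capped track days; big enough to exercise every stage."""
    from datetime import date

    return SimConfig(
        n_individuals=12,
        study_start=date(2019, 5, 5),
        study_end=date(2020, 11, 1),
        raw_days_per_individual=30,
        singleton_rate=0.3,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    sim: SimConfig | None = None            # None -> demo cohort from seed
    latitude: float = 42.225                # array centroid (NW Iberia)
    longitude: float = -8.9
    target_median_error: float = 3.5        # meters
    step_s: float = 80.0
    max_gap_s: float = 1800.0
    philopatry: PhilopatryConfig = field(default_factory=PhilopatryConfig)
    sensitivity_thresholds: tuple = (60, 90, 120)
    kud: KudConfig = field(default_factory=KudConfig)
    mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(
        n_chains=2, n_iter=2000, burn_in=500, thin=5))
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = demo_sim_config(self.seed)


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return _hash_bytes(path.read_bytes())


def _hash_obj(obj) -> str:
    return _hash_bytes(json.dumps(obj, sort_keys=True, default=str).encode())


def _cfg_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _cfg_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all stages, skipping those whose cache key and outputs are
    unchanged. Returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest_path = out / "manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    prev_stages = previous.get("stages", {})
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _hash_obj(_cfg_dict(config)),
        "stages": {},
    }

    def _stage(name: str, params: dict, inputs: list[Path], outputs: list[Path], fn):
        key = _hash_obj({"params": params, "inputs": [_hash_file(p) for p in inputs]})
        prev = prev_stages.get(name)
        if (not force and prev and prev["key"] == key
                and all(Path(p).exists() for p in prev["outputs"])):
            entry = dict(prev, skipped=True)
            manifest["stages"][name] = entry
            log.info("[%s] up to date, skipped", name)
            return
        log.info("[%s] running", name)
        try:
            counts = fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {
            "key": key,
            "outputs": [str(p) for p in outputs],
            "output_hashes": {p.name: _hash_file(p) for p in outputs},
            "row_counts": counts,
            "skipped": False,
        }

    # -- simulate -----------------------------------------------------------
    sim_paths = {k: out / f"{k}.csv" for k in
                 ("individuals", "detections", "positions", "reference_fixes")}

    def do_simulate():
        paths = write_simulated(out, config.sim)
        return {k: int(pd.read_csv(paths[k]).shape[0])
                for k in ("individuals", "detections", "positions")}

    _stage("simulate", {"sim": config.sim.to_dict()}, [],
           list(sim_paths.values()), do_simulate)

    # -- filter detections --------------------------------------------------
    det_out = out / "detections_filtered.csv"

    def do_filter_detections():
        det = telemetry.read_detections(sim_paths["detections"])
        kept, removed = telemetry.filter_single_detections(det)
        write_csv(kept, det_out)
        return {"input": len(det), "retained": len(kept), "removed": len(removed)}

    _stage("filter_detections", {}, [sim_paths["detections"]], [det_out],
           do_filter_detections)

    # -- filter positions ---------------------------------------------------
    pos_out = out / "positions_filtered.csv"
    retention_out = out / "position_retention.csv"

    def do_filter_positions():
        fixes = telemetry.read_positions(sim_paths["positions"])
        ref = telemetry.read_reference_fixes(sim_paths["reference_fixes"])
        cutoffs = telemetry.calibrate_error_cutoff(ref, config.target_median_error)
        kept, summary = telemetry.filter_positions(fixes, cutoffs)
        write_csv(kept, pos_out)
        write_csv(summary, retention_out)
        return {"input": len(fixes), "retained": len(kept)}

    _stage("filter_positions", {"target_median_error": config.target_median_error},
           [sim_paths["positions"], sim_paths["reference_fixes"]],
           [pos_out, retention_out], do_filter_positions)

    # -- classify -----------------------------------------------------------
    phil_out = out / "philopatry.csv"
    sens_out = out / "sensitivity.csv"

    def do_classify():
        det = telemetry.read_detections(det_out)
        series = build_presence(det, (config.sim.study_start, config.sim.study_end))
        labels = classify_all(series, config.philopatry)
        write_csv(labels, phil_out)
        sens = sensitivity(series, config.sensitivity_thresholds,
                           config.philopatry.absence_threshold,
                           config.philopatry.residency_span)
        write_csv(sens.counts.reset_index(), sens_out)
        return {"individuals": len(labels)}

    _stage("classify",
           {"philopatry": _cfg_dict(config.philopatry),
            "thresholds": list(config.sensitivity_thresholds)},
           [det_out], [phil_out, sens_out], do_classify)

    # -- activity -----------------------------------------------------------
    act_out = out / "activity_weekly.csv"

    def do_activity():
        fixes = telemetry.read_positions(pos_out)
        cal = DielCalendar(config.latitude, config.longitude)
        steps = activity_steps(fixes, cal, step=config.step_s, max_gap=config.max_gap_s)
        weekly = aggregate_weekly(steps)
        write_csv(weekly, act_out)
        return {"steps": len(steps), "weekly_rows": len(weekly)}

    _stage("activity",
           {"step": config.step_s, "max_gap": config.max_gap_s,
            "lat": config.latitude, "lon": config.longitude},
           [pos_out], [act_out], do_activity)

    # -- kud ----------------------------------------------------------------
    kud_out = out / "space_weekly.csv"

    def do_kud():
        fixes = telemetry.read_positions(pos_out)
        cal = DielCalendar(config.latitude, config.longitude)
        diel = cal.label_series(fixes["timestamp"])
        weekly = weekly_space_use(fixes, diel, config.kud)
        write_csv(weekly, kud_out)
        return {"weekly_rows": len(weekly)}

    _stage("kud",
           {"kud": _cfg_dict(config.kud), "lat": config.latitude, "lon": config.longitude},
           [pos_out], [kud_out], do_kud)

    # -- fit ----------------------------------------------------------------
    fit_outputs = [out / "model_table.csv", out / "draws.csv", out / "summaries.csv",
                   out / "diagnostics.csv", out / "report.txt"]

    def do_fit():
        act = pd.read_csv(act_out)
        space = pd.read_csv(kud_out)
        meta = telemetry.read_individuals(sim_paths["individuals"])
        labels = pd.read_csv(phil_out)
        table = build_model_table(act, space, meta, labels)
        write_csv(table, fit_outputs[0])
        spec = ModelSpec(mcmc=dataclasses.replace(config.mcmc, seed=config.seed))
        design = build_design(table, spec)
        chains = gibbs_fit(design, spec)
        write_csv(draws_frame(chains, design), fit_outputs[1])
        summaries = summarize(chains, design)
        combined = pd.concat([
            summaries.fixed_effects.assign(block="fixed"),
            summaries.covariances.assign(block="covariance"),
            summaries.repeatability.assign(block="repeatability"),
            summaries.correlation.assign(block="correlation"),
        ])
        write_csv(combined, fit_outputs[2])
        write_csv(diagnostics(chains, design), fit_outputs[3])
        fit_outputs[4].write_text(summaries.report() + "\n")
        return {"model_rows": len(table), "chains": config.mcmc.n_chains}

    _stage("fit",
           {"mcmc": _cfg_dict(config.mcmc), "seed": config.seed},
           [act_out, kud_out, phil_out, sim_paths["individuals"]],
           fit_outputs, do_fit)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
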