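"""End-to-end orchestration: simulate -> metrics -> classify -> population
-> dynamics -> models.

Every stage is a pure function of (inputs, config, seed) and writes only
tidy CSV/JSON tables, so stages are independently testable and a rerun
with an identical config is bit-identical for synthetic input.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import CellRecording, COMMON_SPEEDS
from .metrics import (
    direction_response,
    most_active_speed,
    preferred_direction,
    shape_features,
    spontaneous_rate,
)
from .classify import (
    build_training_set,
    classification_table,
    classify_population,
    inclusion_filter,
    stage1_train,
)
from .population import (
    categorize_population,
    max_speed_proportions,
    normalized_sets,
    population_speed_curve,
    tn_directional_cohort,
    transition_counts,
)
from .dynamics import phase_metrics_table
from .gam import fit_candidates
from .synth import generate_population, truth_table

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

STAGES = ("simulate", "metrics", "classify", "population", "dynamics", "models")


@dataclass
class RunConfig:
    """All knobs of the pipeline in one place.

    ``population`` overrides the default synthetic-population spec (dict in
    the YAML schema); thresholds default to the values used throughout the
    study (alpha 0.05, spline df 8, peak prominence 10%, full motion
    window).
    """

    seed: int = 1
    population: Optional[dict] = None
    out_dir: Optional[Path] = None
    alpha: float = 0.05
    spline_df: int = 8
    prominence: float = 0.1
    motion_window: Optional[tuple] = None  # None = full 0-3,000 ms epoch
    train_stage1: bool = True
    n_extra_training: int = 100
    stages: Sequence[str] = STAGES

    def digest(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "population": self.population,
                "alpha": self.alpha,
                "spline_df": self.spline_df,
                "prominence": self.prominence,
                "motion_window": self.motion_window,
                "train_stage1": self.train_stage1,
                "n_extra_training": self.n_extra_training,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    manifest: dict
    cells: list = field(default_factory=list)
    truths: list = field(default_factory=list)
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    reports: Dict[str, dict] = field(default_factory=dict)


def _write(result: PipelineResult, name: str, frame: pd.DataFrame) -> None:
    result.tables[name] = frame
    if result.config.out_dir is not None:
        out = Path(result.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / f"{name}.csv", index=False)


def _stage_simulate(result: PipelineResult) -> None:
    cells, truths = generate_population(result.config.population, seed=result.config.seed)
    result.cells, result.truths = cells, truths
    _write(result, "ground_truth", truth_table(truths))


def _stage_metrics(result: PipelineResult) -> None:
    cfg = result.config
    rows = []
    for cell in result.cells:
        spont = spontaneous_rate(cell)
        best = most_active_speed(cell, motion_window=cfg.motion_window, spont=spont)
        for speed in cell.speeds:
            resp = direction_response(cell, speed, motion_window=cfg.motion_window,
                                      spont=spont)
            feats = shape_features(resp, df=cfg.spline_df,
                                   prominence_frac=cfg.prominence)
            rows.append({
                "cell_id": cell.cell_id,
                "speed": speed,
                "pd": feats.pd,
                "si": feats.si,
                "inverse_cv": feats.inverse_cv,
                "ap_pd": feats.ap_pd,
                "peak_count": feats.peak_count,
                "spont": spont,
                "max_rate": float(np.max(resp.mean_rate)),
                "most_active": speed == best,
            })
    _write(result, "features", pd.DataFrame(rows))


def _stage_classify(result: PipelineResult) -> None:
    cfg = result.config
    inclusion = [(c.cell_id, inclusion_filter(c)) for c in result.cells]
    _write(result, "inclusion", pd.DataFrame(
        [{"cell_id": cid, "included": bool(r), "reasons": "; ".join(r.reasons)}
         for cid, r in inclusion]
    ))
    model = None
    if cfg.train_stage1:
        labeled = build_training_set(
            result.cells, n_extra=cfg.n_extra_training, seed=cfg.seed,
            motion_window=cfg.motion_window,
        )
        model = stage1_train(labeled, seed=cfg.seed)
        result.reports["stage1_training"] = model.report()
        if cfg.out_dir is not None:
            Path(cfg.out_dir, "stage1_training.json").write_text(
                json.dumps(model.report(), indent=1)
            )
    classified = classify_population(
        result.cells, stage1_model=model, alpha=cfg.alpha,
        motion_window=cfg.motion_window,
    )
    _write(result, "classification", classification_table(classified))


def _stage_population(result: PipelineResult) -> None:
    cfg = result.config
    sets = normalized_sets(result.cells, motion_window=cfg.motion_window)
    _write(result, "speed_curve", population_speed_curve(sets))
    _write(result, "max_speed_proportions", max_speed_proportions(result.cells))

    rn_rows = []
    for s in sets:
        for speed in s.speeds:
            rn_rows.append({
                "cell": s.cell_id,
                "speed": speed,
                "log2_speed": math.log2(speed),
                "rn": float(np.max(s.r[speed])),
            })
    _write(result, "rn_table", pd.DataFrame(rn_rows))

    labels = result.tables["classification"]
    _write(result, "categories", categorize_population(labels))

    pd_table = {
        cid: dict(zip(group["speed"], group["pd"]))
        for cid, group in labels.groupby("cell_id")
    }
    cohort = tn_directional_cohort(labels, pd_table)
    result.reports["tn_cohort"] = {"size": len(cohort), "cells": cohort}
    transitions = []
    for target in (4.0, 256.0, 1024.0):
        table = transition_counts(labels, 32.0, target, cohort=set(cohort).__contains__)
        frame = table.reset_index().melt(
            id_vars=table.index.name, var_name=table.columns.name, value_name="count"
        )
        frame.insert(0, "target_speed", target)
        transitions.append(frame)
    _write(result, "tn_transitions", pd.concat(transitions, ignore_index=True))


def _stage_dynamics(result: PipelineResult) -> None:
    table = phase_metrics_table(result.cells, motion_window=result.config.motion_window)
    _write(result, "phase_metrics", table)


def _stage_models(result: PipelineResult) -> None:
    labels = result.tables["classification"][["cell_id", "speed", "label"]]

    rn = result.tables["rn_table"]
    report = fit_candidates(rn, "rn")
    _write(result, "gam_rn", report.table())

    phase = result.tables["phase_metrics"].merge(
        labels, left_on=["cell_id", "speed"], right_on=["cell_id", "speed"]
    )
    phase = phase[phase["label"] != "unmodulated"]
    for scope in ("all_directions", "nearest_pd"):
        sub = phase[phase["scope"] == scope].copy()
        sub = sub[sub["time_p"].notna() & (sub["time_p"] > 0)]
        timep = pd.DataFrame({
            "cell": sub["cell_id"],
            "log2_speed": np.log2(sub["speed"].astype(float)),
            "log2_timep": np.log2(sub["time_p"].astype(float)),
            "shape": sub["label"],
        })
        _write(result, f"gam_timep_{scope}", fit_candidates(timep, "timep").table())

        melted = sub.melt(
            id_vars=["cell_id", "speed", "label"],
            value_vars=["activity_IT", "activity_TR", "activity_SS"],
            var_name="phase", value_name="activityp",
        )
        melted["phase"] = melted["phase"].str.replace("activity_", "", regex=False)
        act = pd.DataFrame({
            "cell": melted["cell_id"],
            "log2_speed": np.log2(melted["speed"].astype(float)),
            "activityp": melted["activityp"],
            "phase": melted["phase"],
        })
        _write(result, f"gam_activityp_{scope}",
               fit_candidates(act, "activityp").table())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "metrics": _stage_metrics,
    "classify": _stage_classify,
    "population": _stage_population,
    "dynamics": _stage_dynamics,
    "models": _stage_models,
}

# stages later in the chain need tables from earlier ones
_DEPENDENCIES = {
    "metrics": ("simulate",),
    "classify": ("simulate",),
    "population": ("simulate", "classify"),
    "dynamics": ("simulate",),
    "models": ("simulate", "classify", "population", "dynamics"),
}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the requested stages in dependency order and write a manifest."""
    requested = list(config.stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    ordered: List[str] = []
    def add(stage: str) -> None:
        for dep in _DEPENDENCIES.get(stage, ()):
            add(dep)
        if stage not in ordered:
            ordered.append(stage)
    for stage in requested:
        add(stage)

    result = PipelineResult(config=config, manifest={})
    for stage in ordered:
        try:
            _STAGE_FUNCS[stage](result)
        except Exception as err:  # noqa: BLE001 - abort names the stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result.manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "stages": ordered,
        "row_counts": {name: len(t) for name, t in result.tables.items()},
    }
    if config.out_dir is not None:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        Path(config.out_dir, "manifest.json").write_text(
            json.dumps(result.manifest, indent=1)
        )
    return result
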