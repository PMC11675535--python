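"""Canonical data model for grating-sweep protocols and spike trains.

A stimulus *sweep* presents, for every direction x spatiotemporal-frequency
combination, 1 s of blank screen, 1 s of static grating and 3 s of grating
motion.  Spike times are stored per trial, in seconds relative to that
trial's blank onset.  Stimulus speed (deg/s) is never stored in files: it is
always derived as temporal frequency (Hz) / spatial frequency (cpd) and then
bucketed to the nearest nominal protocol speed on a log2 scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSchedule",
    "Trial",
    "CellRecording",
    "Protocol",
    "WIDE_PROTOCOL",
    "DENSE_PROTOCOL",
    "COMMON_SPEEDS",
    "SchemaError",
    "ValidationError",
    "epoch_rate",
    "nominal_speed",
    "read_cell_recording",
    "write_cell_recording",
]

COMMON_SPEEDS = (4.0, 32.0, 256.0, 1024.0)


class SchemaError(ValueError):
    """A delimited input file does not have the expected columns."""


class ValidationError(ValueError):
    """Input data violate an invariant of the data model."""


@dataclass(frozen=True)
class EpochSchedule:
    """Onsets (s) of the blank / static / motion epochs of one trial."""

    blank_onset: float = 0.0
    static_onset: float = 1.0
    motion_onset: float = 2.0
    motion_offset: float = 5.0

    def __post_init__(self) -> None:
        if not (
            self.blank_onset < self.static_onset < self.motion_onset < self.motion_offset
        ):
            raise ValidationError(
                "epoch onsets must be strictly increasing: "
                f"{self.blank_onset}, {self.static_onset}, "
                f"{self.motion_onset}, {self.motion_offset}"
            )

    @property
    def motion_duration(self) -> float:
        return self.motion_offset - self.motion_onset


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation (direction x grating x sweep)."""

    trial_id: str
    direction: float  # degrees in [0, 360)
    spatial_frequency: float  # cycles/degree
    temporal_frequency: float  # Hz
    sweep_index: int
    schedule: EpochSchedule = field(default_factory=EpochSchedule)

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ValidationError(f"{self.trial_id}: spatial_frequency must be > 0")
        if self.temporal_frequency <= 0:
            raise ValidationError(f"{self.trial_id}: temporal_frequency must be > 0")
        if self.sweep_index < 1:
            raise ValidationError(f"{self.trial_id}: sweep_index must be >= 1")
        object.__setattr__(self, "direction", float(self.direction) % 360.0)

    @property
    def speed(self) -> float:
        """Stimulus speed in deg/s: temporal over spatial frequency."""
        return self.temporal_frequency / self.spatial_frequency


@dataclass(frozen=True)
class Protocol:
    """A named set of nominal stimulus speeds."""

    name: str
    speeds: tuple
    sf_range: tuple
    tf_range: tuple
    n_sweeps: int = 10

    def __post_init__(self) -> None:
        if self.n_sweeps > 10:
            raise ValidationError("protocols use at most 10 sweeps")


WIDE_PROTOCOL = Protocol(
    name="wide",
    speeds=(0.062, 0.5, 4.0, 32.0, 256.0, 1024.0),
    sf_range=(0.0155, 0.5),
    tf_range=(0.031, 16.0),
)

DENSE_PROTOCOL = Protocol(
    name="dense",
    speeds=(4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 407.0, 644.0, 1024.0),
    sf_range=(0.0155, 0.25),
    tf_range=(1.0, 16.0),
)

_PROTOCOLS = {"wide": WIDE_PROTOCOL, "dense": DENSE_PROTOCOL}


def get_protocol(name: str) -> Protocol:
    try:
        return _PROTOCOLS[name]
    except KeyError:
        raise ValidationError(f"unknown protocol {name!r}; expected one of {sorted(_PROTOCOLS)}")


def nominal_speed(sf: float, tf: float, protocol: Protocol) -> float:
    """Bucket a (sf, tf) pair to the protocol speed nearest in log2.

    The stimulus grids only approximate the printed nominal speeds
    (e.g. 16 Hz / 0.0155 cpd = 1032.3 deg/s is the nominal 1024 deg/s
    condition), so labeling is by nearest log2 distance.  Idempotent:
    a nominal speed maps to itself.
    """
    raw = tf / sf
    speeds = np.asarray(protocol.speeds, dtype=float)
    return float(speeds[np.argmin(np.abs(np.log2(speeds) - math.log2(raw)))])


@dataclass
class CellRecording:
    """A unit's trials and per-trial spike times (s, relative to blank onset)."""

    cell_id: str
    trials: List[Trial]
    spikes: List[np.ndarray]
    protocol: Protocol = WIDE_PROTOCOL
    angular_offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.spikes):
            raise ValidationError(
                f"{self.cell_id}: {len(self.trials)} trials but {len(self.spikes)} spike lists"
            )
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for trial, sp in zip(self.trials, self.spikes):
            if sp.size and (sp.min() < trial.schedule.blank_onset or sp.max() > trial.schedule.motion_offset):
                raise ValidationError(
                    f"trial {trial.trial_id}: spike outside "
                    f"[{trial.schedule.blank_onset}, {trial.schedule.motion_offset}]"
                )

    def _index(self):
        # condition index built once per recording; trials are immutable
        cached = getattr(self, "_condition_index", None)
        if cached is None:
            cached = {}
            for trial, sp in zip(self.trials, self.spikes):
                speed = nominal_speed(
                    trial.spatial_frequency, trial.temporal_frequency, self.protocol
                )
                cached.setdefault((speed, trial.direction), []).append((trial, sp))
            object.__setattr__(self, "_condition_index", cached)
        return cached

    @property
    def speeds(self) -> List[float]:
        """Sorted nominal speeds present in this recording."""
        return sorted({speed for speed, _ in self._index()})

    def trial_speed(self, trial: Trial) -> float:
        return nominal_speed(trial.spatial_frequency, trial.temporal_frequency, self.protocol)

    @property
    def directions(self) -> np.ndarray:
        """Sorted unique directions (deg) presented to this cell."""
        return np.array(sorted({d for _, d in self._index()}))

    def trials_at(self, speed: float, direction: Optional[float] = None):
        """(trial, spikes) pairs at a nominal speed, optionally one direction."""
        index = self._index()
        if direction is None:
            out = []
            for (sp_key, _), pairs in index.items():
                if sp_key == speed:
                    out.extend(pairs)
        else:
            out = list(index.get((speed, direction % 360.0), []))
        if not out:
            raise KeyError(f"{self.cell_id}: no trials at speed {speed}"
                           + (f", direction {direction}" if direction is not None else ""))
        return out


def epoch_rate(spikes: Sequence[float], window_start: float, window_end: float) -> float:
    """Firing rate (spikes/s) in the half-open window [start, end)."""
    if window_end <= window_start:
        raise ValueError(f"zero or negative window [{window_start}, {window_end})")
    sp = np.asarray(spikes, dtype=float)
    count = int(np.count_nonzero((sp >= window_start) & (sp < window_end)))
    return count / (window_end - window_start)


_TRIAL_COLUMNS = [
    "trial_id",
    "direction",
    "spatial_frequency",
    "temporal_frequency",
    "sweep_index",
    "blank_onset",
    "static_onset",
    "motion_onset",
    "motion_offset",
]


def read_cell_recording(trial_table_path, spikes_path, metadata_path=None) -> CellRecording:
    """Read a cell from a trial-table CSV plus a spike CSV.

    The trial table is comma-delimited with a header row; the spikes file
    has one line per trial: ``trial_id,t1,t2,...`` (possibly just the id for
    silent trials).  An optional JSON sidecar provides cell_id, protocol
    name and an angular offset that is added to all directions at read time
    so downstream analysis always works in the frame where 0 deg is
    temporal-to-nasal motion.
    """
    trial_table_path = Path(trial_table_path)
    spikes_path = Path(spikes_path)
    table = pd.read_csv(trial_table_path, float_precision="round_trip")
    missing = [c for c in _TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{trial_table_path}: missing columns {missing}")

    meta = {}
    if metadata_path is not None:
        meta = json.loads(Path(metadata_path).read_text())
    cell_id = meta.get("cell_id", trial_table_path.stem)
    protocol = get_protocol(meta.get("protocol", "wide"))
    offset = float(meta.get("angular_offset", 0.0))

    spikes_by_id: Dict[str, np.ndarray] = {}
    with open(spikes_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            spikes_by_id[parts[0]] = np.array([float(x) for x in parts[1:] if x != ""])

    trials, spikes = [], []
    known_ids = set()
    for row in table.itertuples(index=False):
        schedule = EpochSchedule(
            blank_onset=float(row.blank_onset),
            static_onset=float(row.static_onset),
            motion_onset=float(row.motion_onset),
            motion_offset=float(row.motion_offset),
        )
        trial = Trial(
            trial_id=str(row.trial_id),
            direction=float(row.direction) + offset,
            spatial_frequency=float(row.spatial_frequency),
            temporal_frequency=float(row.temporal_frequency),
            sweep_index=int(row.sweep_index),
            schedule=schedule,
        )
        known_ids.add(trial.trial_id)
        trials.append(trial)
        spikes.append(spikes_by_id.get(trial.trial_id, np.array([])))

    unknown = set(spikes_by_id) - known_ids
    if unknown:
        raise ValidationError(f"{spikes_path}: unknown trial ids {sorted(unknown)}")

    return CellRecording(cell_id=cell_id, trials=trials, spikes=spikes,
                         protocol=protocol, angular_offset=offset)


def write_cell_recording(cell: CellRecording, trial_table_path, spikes_path,
                         metadata_path=None) -> None:
    """Inverse of :func:`read_cell_recording` (round-trips field-for-field).

    Directions are written back in the as-presented frame (the read-time
    angular offset is removed before writing).
    """
    rows = []
    for trial in cell.trials:
        rows.append({
            "trial_id": trial.trial_id,
            "direction": (trial.direction - cell.angular_offset) % 360.0,
            "spatial_frequency": trial.spatial_frequency,
            "temporal_frequency": trial.temporal_frequency,
            "sweep_index": trial.sweep_index,
            "blank_onset": trial.schedule.blank_onset,
            "static_onset": trial.schedule.static_onset,
            "motion_onset": trial.schedule.motion_onset,
            "motion_offset": trial.schedule.motion_offset,
        })
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(
        trial_table_path, index=False, float_format="%.17g"  # exact round-trip
    )
    with open(spikes_path, "w") as fh:
        for trial, sp in zip(cell.trials, cell.spikes):
            times = ",".join(repr(float(t)) for t in sp)
            fh.write(trial.trial_id + ("," + times if times else "") + "\n")
    if metadata_path is not None:
        Path(metadata_path).write_text(json.dumps({
            "cell_id": cell.cell_id,
            "protocol": cell.protocol.name,
            "angular_offset": cell.angular_offset,
        }, indent=1))
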