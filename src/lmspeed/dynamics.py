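"""Time-resolved response analysis of the 3 s motion epoch.

Responses are binned at 10 ms, spontaneous-subtracted, and normalized
within each cell by the maximum absolute bin rate across all of its
speeds, directions and bins (so the cell's strongest bin maps to +/-1 and
the spontaneous rate to 0).  The motion epoch is segmented into the
initial transient (IT, 40-200 ms), transitional (TR, 200-1,000 ms) and
steady-state (SS, 1,000-3,000 ms) phases, which partition the full-time
window (FT, 40-3,000 ms) under the half-open bin convention.

Two scopes are supported throughout: the across-direction mean trace and
the trace at the tested direction nearest the cell's preferred direction
at that speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import CellRecording
from .metrics import (
    circ_dist,
    direction_response,
    preferred_direction,
    spontaneous_rate,
)

__all__ = [
    "PHASES",
    "FT_WINDOW",
    "BIN_WIDTH",
    "TemporalResponse",
    "PhaseMetrics",
    "bin_edges",
    "temporal_response",
    "cell_temporal_responses",
    "time_to_peak",
    "phase_peak_activity",
    "phase_metrics_table",
]

BIN_WIDTH = 0.010  # s
MOTION_DURATION = 3.0  # s

# phase windows in ms relative to motion onset, half-open [start, end)
FT_WINDOW = (40.0, 3000.0)
PHASES: Dict[str, Tuple[float, float]] = {
    "IT": (40.0, 200.0),
    "TR": (200.0, 1000.0),
    "SS": (1000.0, 3000.0),
}

SCOPES = ("all_directions", "nearest_pd")


@dataclass
class TemporalResponse:
    """Normalized 10 ms-binned trace for one cell x speed x direction."""

    cell_id: str
    speed: float
    direction: float
    rates: np.ndarray  # (300,) normalized, in [-1, 1]
    norm_constant: float  # spikes/s (cell-wide max |bin rate|)


def bin_edges() -> np.ndarray:
    """Edges of the 300 half-open 10 ms bins over the motion epoch (s)."""
    return np.arange(0.0, MOTION_DURATION + BIN_WIDTH / 2, BIN_WIDTH)


def bin_centers_ms() -> np.ndarray:
    edges = bin_edges() * 1000.0
    return (edges[:-1] + edges[1:]) / 2.0


def _raw_binned(cell: CellRecording, speed: float, direction: float,
                spont: float) -> np.ndarray:
    """Across-sweep mean bin rates minus baseline (spikes/s), unnormalized."""
    edges = bin_edges()
    counts = np.zeros(len(edges) - 1)
    n_trials = 0
    for trial, sp in cell.trials_at(speed, direction):
        rel = sp - trial.schedule.motion_onset
        rel = rel[(rel >= 0) & (rel < MOTION_DURATION)]
        counts += np.histogram(rel, bins=edges)[0]
        n_trials += 1
    return counts / (n_trials * BIN_WIDTH) - spont


def cell_temporal_responses(
    cell: CellRecording, spont: Optional[float] = None
) -> Dict[Tuple[float, float], TemporalResponse]:
    """All normalized temporal responses of one cell, keyed (speed, dir)."""
    if spont is None:
        spont = spontaneous_rate(cell)
    raw: Dict[Tuple[float, float], np.ndarray] = {}
    for speed in cell.speeds:
        for direction in cell.directions:
            raw[(speed, direction)] = _raw_binned(cell, speed, direction, spont)
    norm = max(float(np.max(np.abs(r))) for r in raw.values())
    scale = norm if norm > 0 else 1.0
    return {
        key: TemporalResponse(
            cell_id=cell.cell_id, speed=key[0], direction=key[1],
            rates=r / scale, norm_constant=norm,
        )
        for key, r in raw.items()
    }


def temporal_response(
    cell: CellRecording, speed: float, direction: float
) -> TemporalResponse:
    """Normalized binned trace at one (speed, direction)."""
    return cell_temporal_responses(cell)[(speed, direction % 360.0)]


def _window_slice(window_ms: Tuple[float, float]) -> slice:
    # bins are aligned to motion onset, so ms windows map exactly to bins
    return slice(int(window_ms[0] / 1000.0 / BIN_WIDTH),
                 int(window_ms[1] / 1000.0 / BIN_WIDTH))


def scope_trace(
    responses: Dict[Tuple[float, float], TemporalResponse],
    speed: float,
    scope: str,
    pd_at_speed: float = math.nan,
) -> np.ndarray:
    """The trace a phase metric is computed on, for one speed and scope."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    at_speed = {d: r for (s, d), r in responses.items() if s == speed}
    if not at_speed:
        raise KeyError(f"no temporal responses at speed {speed}")
    if scope == "all_directions":
        return np.mean([r.rates for r in at_speed.values()], axis=0)
    if math.isnan(pd_at_speed):
        raise ValueError("nearest_pd scope requires a defined preferred direction")
    directions = np.array(sorted(at_speed))
    nearest = float(directions[np.argmin(circ_dist(directions, pd_at_speed))])
    return at_speed[nearest].rates


def time_to_peak(trace: np.ndarray, window_ms: Tuple[float, float] = FT_WINDOW) -> float:
    """Center (ms) of the first maximal bin within the window; NaN if flat."""
    sl = _window_slice(window_ms)
    segment = np.asarray(trace)[sl]
    if np.all(segment == segment[0]):
        return math.nan
    first = int(np.argmax(segment))  # argmax returns the earliest maximum
    centers = bin_centers_ms()[sl]
    return float(centers[first])


def phase_peak_activity(trace: np.ndarray) -> Dict[str, float]:
    """Max normalized bin rate within each of IT, TR and SS.

    The phases partition FT, so the max over the three phases equals the
    max over the full-time window.
    """
    return {
        name: float(np.max(np.asarray(trace)[_window_slice(window)]))
        for name, window in PHASES.items()
    }


def phase_metrics_table(
    cells: Sequence[CellRecording], motion_window=None
) -> pd.DataFrame:
    """Tidy per cell x speed x scope table of time_p and phase activities.

    The preferred direction used for the nearest-PD scope is the
    vector-sum PD at that speed; rows with undefined PD carry NaNs for the
    nearest-PD scope.
    """
    rows = []
    for cell in cells:
        spont = spontaneous_rate(cell)
        responses = cell_temporal_responses(cell, spont=spont)
        for speed in cell.speeds:
            resp = direction_response(cell, speed, motion_window=motion_window,
                                      spont=spont)
            pd_val = preferred_direction(resp)
            for scope in SCOPES:
                if scope == "nearest_pd" and math.isnan(pd_val):
                    continue
                trace = scope_trace(responses, speed, scope, pd_at_speed=pd_val)
                activity = phase_peak_activity(trace)
                rows.append({
                    "cell_id": cell.cell_id,
                    "speed": speed,
                    "scope": scope,
                    "pd": pd_val,
                    "time_p": time_to_peak(trace),
                    "activity_IT": activity["IT"],
                    "activity_TR": activity["TR"],
                    "activity_SS": activity["SS"],
                })
    return pd.DataFrame(rows)
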