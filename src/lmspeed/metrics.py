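"""Tuning-curve metrics for direction responses at a single stimulus speed.

All metrics operate on spontaneous-subtracted mean firing rates at the eight
tested directions (45 deg apart).  Suppressed (negative) rates are floored
at zero inside the vector-sum computations (preferred direction, sensitivity
index, AP/PD ratio) because those formulas presuppose nonnegative rates;
the signed rates are preserved on the response object for normalization.

Metric definitions
------------------
preferred direction (PD)
    four-quadrant arctangent of the vector sum ``(sum FR_n sin t_n,
    sum FR_n cos t_n)``.
sensitivity index (SI)
    normalized mean-resultant length, 0 (uniform) to 1 (single direction).
AP/PD
    rate at the tested direction nearest PD+180 over the rate nearest PD.
inverse CV
    mean over directions divided by the (n-1) standard deviation; flagged
    infinite for perfectly flat curves.
peak count
    circular local maxima of a periodized natural-cubic-spline fit with
    prominence at least 10% of the curve range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import patsy
from scipy.signal import find_peaks

from .io import CellRecording, epoch_rate

__all__ = [
    "DirectionResponse",
    "ShapeFeatures",
    "circ_dist",
    "spontaneous_rate",
    "spontaneous_replicates",
    "direction_response",
    "preferred_direction",
    "sensitivity_index",
    "ap_pd_ratio",
    "inverse_cv",
    "fit_tuning_spline",
    "peak_count",
    "shape_features",
    "most_active_speed",
    "pd_direction_rate",
]

# spontaneous window: second half of the 1 s static-grating epoch, when the
# onset transient (up to ~200 ms) has decayed
SPONT_WINDOW = (0.5, 1.0)  # s after static onset


def circ_dist(a, b) -> np.ndarray:
    """Absolute circular distance in degrees, in [0, 180]."""
    return np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class DirectionResponse:
    """Spontaneous-subtracted direction tuning of one cell at one speed."""

    cell_id: str
    speed: float
    directions: np.ndarray  # (8,) degrees, sorted
    mean_rate: np.ndarray  # (8,) spikes/s, signed
    sweep_rates: List[np.ndarray]  # per direction, per-sweep rates
    spont: float
    n_sweeps: np.ndarray  # (8,) ints

    def floored(self) -> np.ndarray:
        return np.maximum(self.mean_rate, 0.0)


@dataclass
class ShapeFeatures:
    """The classification features for one cell x speed response."""

    pd: float  # degrees; NaN when undefined
    si: float  # [0, 1]; NaN when undefined
    inverse_cv: float  # may be inf for flat curves
    ap_pd: float  # NaN when PD rate <= 0
    peak_count: int
    peak_ratio: float = math.inf  # largest / second-largest peak height

    def as_array(self) -> np.ndarray:
        """(si, inverse_cv, ap_pd, peak_count) with flags mapped to numbers."""
        si = 0.0 if math.isnan(self.si) else self.si
        icv = self.inverse_cv
        if math.isinf(icv):
            icv = 1e3
        elif math.isnan(icv):
            icv = 0.0
        ap = 0.0 if math.isnan(self.ap_pd) else min(self.ap_pd, 1e3)
        return np.array([si, icv, ap, float(self.peak_count)])


FEATURE_NAMES = ("si", "inverse_cv", "ap_pd", "peak_count")


def spontaneous_rate(cell: CellRecording) -> float:
    """Baseline rate: mean over all trials in the 500-1,000 ms static window."""
    return float(np.mean(spontaneous_replicates(cell)))


def spontaneous_replicates(cell: CellRecording) -> np.ndarray:
    """Per-trial firing rates in the spontaneous window (spikes/s)."""
    if not cell.trials:
        raise ValueError(f"{cell.cell_id}: no trials")
    rates = []
    for trial, sp in zip(cell.trials, cell.spikes):
        start = trial.schedule.static_onset + SPONT_WINDOW[0]
        end = trial.schedule.static_onset + SPONT_WINDOW[1]
        rates.append(epoch_rate(sp, start, end))
    return np.asarray(rates)


def direction_response(
    cell: CellRecording,
    speed: float,
    motion_window: Optional[Tuple[float, float]] = None,
    spont: Optional[float] = None,
) -> DirectionResponse:
    """Per-direction mean (and per-sweep) motion rates minus baseline.

    ``motion_window`` is (start, end) in s relative to motion onset; the
    default is the full 3 s epoch.  Pass (0.04, 3.0) to exclude the first
    40 ms transient.
    """
    if spont is None:
        spont = spontaneous_rate(cell)
    directions = cell.directions
    sweep_rates: List[np.ndarray] = []
    mean_rate = np.empty(len(directions))
    n_sweeps = np.empty(len(directions), dtype=int)
    for i, direction in enumerate(directions):
        rates = []
        for trial, sp in cell.trials_at(speed, direction):
            if motion_window is None:
                start, end = trial.schedule.motion_onset, trial.schedule.motion_offset
            else:
                start = trial.schedule.motion_onset + motion_window[0]
                end = trial.schedule.motion_onset + motion_window[1]
            rates.append(epoch_rate(sp, start, end) - spont)
        sweep_rates.append(np.asarray(rates))
        mean_rate[i] = np.mean(rates)
        n_sweeps[i] = len(rates)
    return DirectionResponse(
        cell_id=cell.cell_id,
        speed=speed,
        directions=directions,
        mean_rate=mean_rate,
        sweep_rates=sweep_rates,
        spont=spont,
        n_sweeps=n_sweeps,
    )


def _vector_sum(resp: DirectionResponse) -> Tuple[float, float, float]:
    rates = resp.floored()
    theta = np.deg2rad(resp.directions)
    s = float(np.sum(rates * np.sin(theta)))
    c = float(np.sum(rates * np.cos(theta)))
    total = float(np.sum(rates))
    # snap float-roundoff residue of exactly balanced curves to zero, so a
    # uniform response has SI exactly 0
    tol = 1e-9 * total
    if abs(s) < tol:
        s = 0.0
    if abs(c) < tol:
        c = 0.0
    return s, c, total


def preferred_direction(resp: DirectionResponse) -> float:
    """Vector-sum preferred direction in [0, 360); NaN when all rates <= 0."""
    s, c, total = _vector_sum(resp)
    if total <= 0:
        return math.nan
    return math.degrees(math.atan2(s, c)) % 360.0


def sensitivity_index(resp: DirectionResponse) -> float:
    """Normalized mean-resultant length of the direction response, in [0, 1]."""
    s, c, total = _vector_sum(resp)
    if total <= 0:
        return math.nan
    return min(math.hypot(s, c) / total, 1.0)


def ap_pd_ratio(resp: DirectionResponse, pd: float) -> float:
    """Rate at the tested direction nearest PD+180 over that nearest PD."""
    if math.isnan(pd):
        return math.nan
    rates = resp.floored()
    i_pd = int(np.argmin(circ_dist(resp.directions, pd)))
    i_ap = int(np.argmin(circ_dist(resp.directions, pd + 180.0)))
    if rates[i_pd] <= 0:
        return math.nan
    return float(rates[i_ap] / rates[i_pd])


def inverse_cv(resp: DirectionResponse) -> float:
    """Mean over directions divided by the sample SD; inf for flat curves."""
    if len(resp.mean_rate) < 2:
        raise ValueError("inverse CV requires at least 2 directions")
    sd = float(np.std(resp.mean_rate, ddof=1))
    if sd == 0:
        return math.inf
    return float(np.mean(resp.mean_rate)) / sd


def fit_tuning_spline(
    directions: Sequence[float],
    rates: Sequence[float],
    df: int = 8,
    grid: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Periodized natural-cubic-spline fit of an 8-point tuning curve.

    The circular data are tripled over [-360, 720) and a natural cubic
    regression spline with ``df`` degrees of freedom *per period* is fitted
    by least squares; the central period is evaluated on a 1 deg grid.
    With df=8 on 8 distinct points the basis has as many columns as tripled
    data, so the central period near-interpolates the data.
    """
    if df not in (7, 8):
        raise ValueError("df must be 7 or 8")
    directions = np.asarray(directions, dtype=float)
    rates = np.asarray(rates, dtype=float)
    order = np.argsort(directions)
    x_sorted = directions[order]
    y = np.tile(rates[order], 3)
    total_df = 3 * df  # basis spans three periods
    pinv, design_info, default_grid_X = _spline_design(tuple(x_sorted), total_df)
    beta = pinv @ y
    if grid is None:
        grid = np.arange(0.0, 360.0)
        grid_X = default_grid_X
    else:
        (new_design,) = patsy.build_design_matrices(
            [design_info], {"x": np.asarray(grid, dtype=float), "df": total_df}
        )
        grid_X = np.column_stack([np.ones(len(grid)), np.asarray(new_design)])
    return np.asarray(grid, dtype=float), grid_X @ beta


@lru_cache(maxsize=32)
def _spline_design(x_sorted: tuple, total_df: int):
    """Cached periodized spline design for one set of tested directions."""
    base = np.asarray(x_sorted, dtype=float)
    x = np.concatenate([base - 360.0, base, base + 360.0])
    design = patsy.dmatrix("cr(x, df=df) - 1", {"x": x, "df": total_df},
                           return_type="dataframe")
    X = np.column_stack([np.ones(len(x)), design.to_numpy()])
    grid = np.arange(0.0, 360.0)
    (grid_design,) = patsy.build_design_matrices(
        [design.design_info], {"x": grid, "df": total_df}
    )
    grid_X = np.column_stack([np.ones(len(grid)), np.asarray(grid_design)])
    return np.linalg.pinv(X), design.design_info, grid_X


def peak_count(
    curve: np.ndarray, prominence_frac: float = 0.1, return_heights: bool = False
):
    """Circular local maxima with prominence >= ``prominence_frac`` of range.

    ``curve`` is a dense tuning curve over one full period (uniform grid).
    A constant curve has zero peaks.
    """
    curve = np.asarray(curve, dtype=float)
    rng = float(curve.max() - curve.min())
    if rng <= 1e-8 * max(1.0, float(np.abs(curve).max())):  # flat (to roundoff)
        return (0, np.array([])) if return_heights else 0
    n = len(curve)
    wrapped = np.concatenate([curve, curve, curve])
    idx, _props = find_peaks(wrapped, prominence=prominence_frac * rng)
    idx = idx[(idx >= n) & (idx < 2 * n)] - n
    if return_heights:
        return len(idx), curve[idx]
    return len(idx)


def shape_features(
    resp: DirectionResponse, df: int = 8, prominence_frac: float = 0.1
) -> ShapeFeatures:
    """Compute the full classification feature set for one response."""
    pd = preferred_direction(resp)
    si = sensitivity_index(resp)
    icv = inverse_cv(resp)
    ap = ap_pd_ratio(resp, pd)
    _, curve = fit_tuning_spline(resp.directions, resp.mean_rate, df=df)
    n_peaks, heights = peak_count(curve, prominence_frac, return_heights=True)
    if n_peaks >= 2:
        top = np.sort(np.maximum(heights, 0.0))[::-1]
        peak_ratio = math.inf if top[1] <= 0 else float(top[0] / top[1])
    else:
        peak_ratio = math.inf
    return ShapeFeatures(pd=pd, si=si, inverse_cv=icv, ap_pd=ap,
                         peak_count=n_peaks, peak_ratio=peak_ratio)


def pd_direction_rate(resp: DirectionResponse) -> float:
    """Spontaneous-subtracted rate at the tested direction nearest the PD.

    Falls back to the largest floored rate when the PD is undefined.
    """
    pd = preferred_direction(resp)
    rates = resp.floored()
    if math.isnan(pd):
        return float(rates.max())
    return float(rates[int(np.argmin(circ_dist(resp.directions, pd)))])


def most_active_speed(
    cell: CellRecording,
    motion_window: Optional[Tuple[float, float]] = None,
    spont: Optional[float] = None,
) -> float:
    """Speed with the greatest PD-direction response; ties go to the slower."""
    if spont is None:
        spont = spontaneous_rate(cell)
    best_speed, best_rate = None, -math.inf
    for speed in cell.speeds:  # sorted ascending, so strict > keeps the slower
        resp = direction_response(cell, speed, motion_window=motion_window, spont=spont)
        rate = pd_direction_rate(resp)
        if rate > best_rate:
            best_speed, best_rate = speed, rate
    return float(best_speed)
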