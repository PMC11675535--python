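"""Population-level analyses across stimulus speeds.

Covers the normalized directional response R_n (each cell's signed,
spontaneous-subtracted rates scaled by its maximum absolute response over
all speeds and directions, so values live in [-1, 1] with spontaneous at
0), the population speed-tuning curve, the proportion of cells maximally
responsive at each speed, preferred-direction stability across speeds, the
four across-speed tuning categories, and classification transition tables
between speeds (the basis of Sankey diagrams).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import CellRecording, COMMON_SPEEDS
from .metrics import (
    DirectionResponse,
    circ_dist,
    direction_response,
    most_active_speed,
    preferred_direction,
    spontaneous_rate,
)

__all__ = [
    "NormalizedResponseSet",
    "AcrossSpeedCategory",
    "CATEGORIES",
    "normalize_directional",
    "population_speed_curve",
    "max_speed_proportions",
    "pd_stability",
    "across_speed_category",
    "transition_counts",
    "tn_directional_cohort",
]

CATEGORIES = ("dir_to_omni", "mostly_directional", "mostly_omni", "variable")

PD_STABILITY_ZONE = 22.5  # degrees, inclusive
TN_ZONE = 22.5  # |PD| <= 22.5 deg counts as temporal-to-nasal


@dataclass
class NormalizedResponseSet:
    """R_n for one cell: signed rates scaled to max |rate| = 1."""

    cell_id: str
    speeds: List[float]
    directions: np.ndarray
    r: Dict[float, np.ndarray]  # speed -> (8,) normalized signed rates
    norm_constant: float  # spikes/s
    flat: bool = False  # all-zero cell (norm_constant 0)


@dataclass
class AcrossSpeedCategory:
    cell_id: str
    category: str
    labels: Dict[float, str]  # label at each common speed


def normalize_directional(
    responses: Sequence[DirectionResponse], cell_id: Optional[str] = None
) -> NormalizedResponseSet:
    """Scale one cell's signed rates by its max absolute response.

    Idempotent: normalizing an already-normalized set returns it unchanged
    (the norm constant of a normalized set is 1).
    """
    if not responses:
        raise ValueError("no responses to normalize")
    if cell_id is None:
        cell_id = responses[0].cell_id
    norm = max(float(np.max(np.abs(r.mean_rate))) for r in responses)
    flat = norm == 0
    scale = 1.0 if flat else norm
    return NormalizedResponseSet(
        cell_id=cell_id,
        speeds=[r.speed for r in responses],
        directions=responses[0].directions.copy(),
        r={r.speed: r.mean_rate / scale for r in responses},
        norm_constant=norm,
        flat=flat,
    )


def normalized_sets(
    cells: Sequence[CellRecording], motion_window=None
) -> List[NormalizedResponseSet]:
    out = []
    for cell in cells:
        spont = spontaneous_rate(cell)
        resps = [
            direction_response(cell, s, motion_window=motion_window, spont=spont)
            for s in cell.speeds
        ]
        out.append(normalize_directional(resps, cell_id=cell.cell_id))
    return out


def population_speed_curve(sets: Sequence[NormalizedResponseSet]) -> pd.DataFrame:
    """Mean +/- SEM over cells of the per-cell max R_n at each speed."""
    per_speed: Dict[float, List[float]] = {}
    for s in sets:
        for speed in s.speeds:
            per_speed.setdefault(speed, []).append(float(np.max(s.r[speed])))
    rows = []
    for speed in sorted(per_speed):
        vals = np.asarray(per_speed[speed])
        sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({
            "speed": speed,
            "n_cells": len(vals),
            "mean_max_rn": float(np.mean(vals)),
            "sem": sem,
        })
    return pd.DataFrame(rows)


def max_speed_proportions(cells: Sequence[CellRecording]) -> pd.DataFrame:
    """Counts tested / maximally responsive and their ratio per speed."""
    tested: Dict[float, int] = {}
    maximal: Dict[float, int] = {}
    for cell in cells:
        best = most_active_speed(cell)
        for speed in cell.speeds:
            tested[speed] = tested.get(speed, 0) + 1
        maximal[best] = maximal.get(best, 0) + 1
    rows = []
    for speed in sorted(tested):
        n_max = maximal.get(speed, 0)
        rows.append({
            "speed": speed,
            "n_tested": tested[speed],
            "n_maximal": n_max,
            "proportion": n_max / tested[speed],
        })
    return pd.DataFrame(rows)


def pd_stability(
    pds: Dict[float, float],
    reference_speed: float,
    zone: float = PD_STABILITY_ZONE,
) -> Dict[float, Optional[bool]]:
    """Whether the PD at each speed stays within +/-zone of the reference PD.

    ``pds`` maps speed -> preferred direction (NaN when undefined).  The
    boundary is inclusive; undefined PDs yield None (excluded from any
    fraction downstream).  Wraparound is circular: 350 vs 10 deg is 20 deg.
    """
    ref = pds.get(reference_speed, math.nan)
    out: Dict[float, Optional[bool]] = {}
    for speed, pd_val in pds.items():
        if math.isnan(pd_val) or math.isnan(ref):
            out[speed] = None
        else:
            out[speed] = bool(circ_dist(pd_val, ref) <= zone)
    return out


def across_speed_category(
    labels: Dict[float, str], common_speeds: Sequence[float] = COMMON_SPEEDS
) -> Optional[AcrossSpeedCategory]:
    """Assign one of four across-speed tuning categories.

    Precedence (each rule only applies if no earlier rule matched):
      1. dir_to_omni        - directional at 32 and omnidirectional at 256;
      2. mostly_directional - directional at 32 and at 4 or 256;
      3. mostly_omni        - omnidirectional at 32 and at >= 2 of the
                              other three common speeds;
      4. variable           - everything else.
    Returns None when a common-speed label is missing (category withheld).
    """
    if any(s not in labels for s in common_speeds):
        return None
    sub = {s: labels[s] for s in common_speeds}
    cell_labels = dict(sub)
    at = sub.get
    if at(32.0) == "directional" and at(256.0) == "omnidirectional":
        cat = "dir_to_omni"
    elif at(32.0) == "directional" and (
        at(4.0) == "directional" or at(256.0) == "directional"
    ):
        cat = "mostly_directional"
    elif at(32.0) == "omnidirectional" and sum(
        at(s) == "omnidirectional" for s in (4.0, 256.0, 1024.0)
    ) >= 2:
        cat = "mostly_omni"
    else:
        cat = "variable"
    return AcrossSpeedCategory(cell_id="", category=cat, labels=cell_labels)


def categorize_population(
    label_table: pd.DataFrame, common_speeds: Sequence[float] = COMMON_SPEEDS
) -> pd.DataFrame:
    """Across-speed categories for every fully-labeled cell.

    ``label_table`` needs columns cell_id, speed, label (one row per
    response).  The assignment is a partition: every fully-labeled cell
    receives exactly one category.
    """
    rows = []
    for cell_id, group in label_table.groupby("cell_id", sort=True):
        labels = dict(zip(group["speed"].astype(float), group["label"]))
        cat = across_speed_category(labels, common_speeds)
        if cat is None:
            continue
        cat.cell_id = cell_id
        row = {"cell_id": cell_id, "category": cat.category}
        row.update({f"label_{int(s)}": cat.labels[s] for s in common_speeds})
        rows.append(row)
    return pd.DataFrame(rows)


def transition_counts(
    label_table: pd.DataFrame,
    speed_a: float,
    speed_b: float,
    cohort: Optional[Callable[[str], bool]] = None,
) -> pd.DataFrame:
    """Label x label transition table between two speeds over a cohort.

    ``cohort`` is a predicate on cell_id (None keeps every cell that has
    labels at both speeds).  Row sums equal the cohort size, so chained
    tables conserve cohort size across any sequence of speeds.
    """
    wide = label_table.pivot_table(
        index="cell_id", columns="speed", values="label", aggfunc="first"
    )
    if speed_a not in wide.columns or speed_b not in wide.columns:
        raise KeyError(f"labels missing at speed {speed_a} or {speed_b}")
    wide = wide.dropna(subset=[speed_a, speed_b])
    if cohort is not None:
        wide = wide[[cohort(cid) for cid in wide.index]]
    from .classify import ALL_LABELS

    table = pd.DataFrame(
        0, index=list(ALL_LABELS), columns=list(ALL_LABELS), dtype=int
    )
    for _, row in wide.iterrows():
        table.loc[row[speed_a], row[speed_b]] += 1
    table.index.name = f"label_at_{speed_a}"
    table.columns.name = f"label_at_{speed_b}"
    return table


def tn_directional_cohort(
    label_table: pd.DataFrame,
    pd_table: Dict[str, Dict[float, float]],
    speed: float = 32.0,
    tn_zone: float = TN_ZONE,
) -> List[str]:
    """Cells directional at ``speed`` with PD within ``tn_zone`` of 0 deg.

    ``pd_table`` maps cell_id -> {speed: preferred direction}.  This is the
    temporal-to-nasal cohort used for transition analyses.
    """
    cohort = []
    for cell_id, group in label_table.groupby("cell_id", sort=True):
        labels = dict(zip(group["speed"].astype(float), group["label"]))
        if labels.get(speed) != "directional":
            continue
        pd_val = pd_table.get(cell_id, {}).get(speed, math.nan)
        if not math.isnan(pd_val) and circ_dist(pd_val, 0.0) <= tn_zone:
            cohort.append(cell_id)
    return cohort
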