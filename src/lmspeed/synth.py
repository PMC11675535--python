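"""Synthetic population of direction x speed tuned spiking neurons.

Each cell is an inhomogeneous Poisson process whose intensity factorizes
into a direction term (von Mises bump, or an equal mixture of two opposite
bumps for bidirectional cells), a log-Gaussian speed term, and a temporal
envelope with a speed-dependent initial transient riding on a saturating
sustained component:

    r(t, th, v) = spont + G_dir(th; pd, kappa(v)) * G_speed(v)
                        * [A_IT(v) * alpha(t) + sustained_gain * sigma(t)]

with ``kappa(v) = kappa0 * kappa_decay ** log2(v / speed_center)`` so that
directional sharpness can decay with speed (the directional-to-omni
archetype), ``alpha`` an alpha-function pulse peaking at
``latency(v) = latency_base - latency_slope * log2(v)`` (floored at 10 ms)
and ``sigma(t) = 1 - exp(-t / tau_sustained)``.

Five archetypes cover the response families seen in pretectal recordings:
directional, directional-to-omnidirectional, bidirectional,
omnidirectional (kappa 0 at all speeds) and unmodulated (zero motion gain).
Ground-truth per-speed shape labels are derived from the noiseless rate
model, so every downstream stage can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .io import (
    CellRecording,
    EpochSchedule,
    Protocol,
    Trial,
    get_protocol,
)

__all__ = [
    "ArchetypeParams",
    "GroundTruth",
    "ARCHETYPES",
    "rate_function",
    "simulate_cell",
    "generate_population",
    "default_population_config",
    "true_shape_label",
    "noiseless_direction_curve",
]

ARCHETYPES = ("directional", "dir_to_omni", "bidirectional", "omnidirectional", "unmodulated")

DIRECTIONS = np.arange(0.0, 360.0, 45.0)

MIN_LATENCY = 0.010  # s
TAU_SUSTAINED = 0.150  # s, rise time constant of the sustained envelope
UNMODULATED_THRESHOLD = 5.0  # spikes/s; below this a condition is truly unmodulated


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters of one synthetic cell."""

    archetype: str
    pd: float = 0.0  # degrees
    kappa0: float = 4.0  # von Mises concentration at speed_center
    kappa_decay: float = 1.0  # multiplicative decay per octave above speed_center
    speed_center: float = 32.0  # deg/s
    speed_sigma: float = 3.0  # octaves
    peak_gain: float = 60.0  # spikes/s
    spont: float = 6.0  # spikes/s
    sustained_gain: float = 1.0
    transient_gain_slope: float = 0.3  # per octave
    it_gain: float = 1.5  # transient amplitude at speed_center
    latency_base: float = 180.0  # ms at 1 deg/s
    latency_slope: float = 14.0  # ms per octave
    bidir_weight: float = 0.5  # weight of the pd bump in bidirectional mixtures

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.kappa0 < 0 or self.spont < 0 or self.peak_gain < 0:
            raise ValueError("kappa0, spont and peak_gain must be nonnegative")
        if self.archetype == "omnidirectional" and self.kappa0 != 0:
            raise ValueError("omnidirectional archetype requires kappa0 = 0")
        if self.archetype == "unmodulated" and self.peak_gain != 0:
            raise ValueError("unmodulated archetype requires peak_gain = 0")

    def kappa(self, speed: float) -> float:
        """Direction concentration at a given speed (nonnegative).

        Decay applies only above speed_center: tuning broadens toward fast
        speeds but does not sharpen without bound toward slow ones.
        """
        if self.kappa0 == 0:
            return 0.0
        octaves = max(math.log2(speed / self.speed_center), 0.0)
        return max(self.kappa0 * self.kappa_decay ** octaves, 0.0)

    def latency(self, speed: float) -> float:
        """Transient peak latency (s) at a given speed, floored at 10 ms."""
        lat_ms = self.latency_base - self.latency_slope * math.log2(speed)
        return max(lat_ms / 1000.0, MIN_LATENCY)

    def transient_gain(self, speed: float) -> float:
        """Transient amplitude, growing with speed for positive slope."""
        return self.it_gain * (speed / self.speed_center) ** self.transient_gain_slope

    def speed_gain(self, speed: float) -> float:
        """Log-Gaussian speed tuning, peak_gain at speed_center (spikes/s)."""
        x = math.log2(speed) - math.log2(self.speed_center)
        return self.peak_gain * math.exp(-(x * x) / (2.0 * self.speed_sigma ** 2))

    def direction_gain(self, direction, speed: float) -> np.ndarray:
        """Direction tuning in [0, 1], normalized to peak 1."""
        delta = np.deg2rad(np.asarray(direction, dtype=float) - self.pd)
        kappa = self.kappa(speed)
        if self.archetype == "bidirectional":
            w = self.bidir_weight
            bump = w * np.exp(kappa * (np.cos(delta) - 1.0)) + (1.0 - w) * np.exp(
                kappa * (-np.cos(delta) - 1.0)
            )
            norm = max(w, 1.0 - w) + min(w, 1.0 - w) * math.exp(-2.0 * kappa)
            return bump / norm
        return np.exp(kappa * (np.cos(delta) - 1.0))


@dataclass
class GroundTruth:
    """Generative truth for one synthetic cell."""

    cell_id: str
    archetype: str
    pd: float
    params: ArchetypeParams
    labels: Dict[float, str] = field(default_factory=dict)  # speed -> shape label


def _alpha_pulse(t: np.ndarray, t_peak: float) -> np.ndarray:
    """Alpha function normalized to peak 1 at t_peak; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    out = (t / t_peak) * np.exp(1.0 - t / t_peak)
    return np.where(t >= 0, out, 0.0)


def _sustained(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t >= 0, 1.0 - np.exp(-t / TAU_SUSTAINED), 0.0)


def rate_function(t, direction, speed: float, params: ArchetypeParams) -> np.ndarray:
    """Instantaneous firing rate (spikes/s), t in s since motion onset."""
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 3.0)):
        raise ValueError("t must lie within the 3 s motion epoch")
    if speed <= 0:
        raise ValueError("speed must be positive")
    envelope = params.transient_gain(speed) * _alpha_pulse(
        t, params.latency(speed)
    ) + params.sustained_gain * _sustained(t)
    rate = params.spont + params.direction_gain(direction, speed) * params.speed_gain(
        speed
    ) * envelope
    return np.maximum(rate, 0.0)


def mean_motion_modulation(params: ArchetypeParams, speed: float,
                           directions: np.ndarray = DIRECTIONS) -> np.ndarray:
    """Noiseless motion-epoch mean rate above spontaneous, per direction."""
    t = np.arange(0.0005, 3.0, 0.001)
    envelope = params.transient_gain(speed) * _alpha_pulse(t, params.latency(speed)) \
        + params.sustained_gain * _sustained(t)
    mean_env = float(np.mean(envelope))
    return params.direction_gain(directions, speed) * params.speed_gain(speed) * mean_env


def noiseless_direction_curve(params: ArchetypeParams, speed: float) -> np.ndarray:
    """Expected spontaneous-subtracted tuning curve at the 8 directions."""
    return mean_motion_modulation(params, speed)


def true_shape_label(params: ArchetypeParams, speed: float) -> str:
    """Ground-truth shape label from the noiseless rate model.

    A condition whose best-direction modulation stays below 5 spikes/s (the
    inclusion bound) is truly unmodulated; otherwise the deterministic rule
    classifier applied to the noiseless tuning curve defines the label.
    """
    from .classify import rule_classifier  # local import: classify pulls in xgboost
    from .metrics import DirectionResponse, shape_features

    rates = noiseless_direction_curve(params, speed)
    if params.peak_gain == 0 or float(rates.max()) < UNMODULATED_THRESHOLD:
        return "unmodulated"
    resp = DirectionResponse(
        cell_id="truth",
        speed=speed,
        directions=DIRECTIONS.copy(),
        mean_rate=rates,
        sweep_rates=[np.array([r]) for r in rates],
        spont=params.spont,
        n_sweeps=np.ones(len(rates), dtype=int),
    )
    return rule_classifier(shape_features(resp))


def _cell_rng(master_seed: int, cell_index: int) -> np.random.Generator:
    # stable per-cell stream: populations extend without disturbing old cells
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(cell_index)]))


def simulate_cell(
    params: ArchetypeParams,
    protocol: Protocol,
    n_sweeps: int = 10,
    seed: int = 0,
    cell_id: str = "cell",
    cell_index: int = 0,
) -> Tuple[CellRecording, GroundTruth]:
    """Draw a spiking recording from the rate model by Poisson thinning.

    Blank and static epochs fire at the spontaneous rate; the motion epoch
    follows :func:`rate_function`.  Thinning against a per-trial intensity
    ceiling is exact for any bounded intensity.  Trial order is randomized
    within each sweep, mirroring randomized stimulus ordering.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = _cell_rng(seed, cell_index)
    schedule = EpochSchedule()
    sf_lo, sf_hi = protocol.sf_range
    trials: List[Trial] = []
    spikes: List[np.ndarray] = []
    for sweep in range(1, n_sweeps + 1):
        conditions = [(sp, d) for sp in protocol.speeds for d in DIRECTIONS]
        rng.shuffle(conditions)
        for k, (speed, direction) in enumerate(conditions):
            # any (sf, tf) on the grid realizing this nominal speed
            sf = min(max(math.sqrt(16.0 / speed) / 8.0, sf_lo), sf_hi)
            tf = sf * speed
            trial = Trial(
                trial_id=f"{cell_id}-s{sweep:02d}-c{k:02d}",
                direction=direction,
                spatial_frequency=sf,
                temporal_frequency=tf,
                sweep_index=sweep,
                schedule=schedule,
            )
            trials.append(trial)
            spikes.append(_draw_trial_spikes(rng, params, speed, direction, schedule))
    recording = CellRecording(
        cell_id=cell_id, trials=trials, spikes=spikes, protocol=protocol
    )
    truth = GroundTruth(
        cell_id=cell_id,
        archetype=params.archetype,
        pd=params.pd,
        params=params,
        labels={sp: true_shape_label(params, sp) for sp in protocol.speeds},
    )
    return recording, truth


def _draw_trial_spikes(
    rng: np.random.Generator,
    params: ArchetypeParams,
    speed: float,
    direction: float,
    schedule: EpochSchedule,
) -> np.ndarray:
    pre_duration = schedule.motion_onset - schedule.blank_onset
    out = []
    if params.spont > 0:
        n_pre = rng.poisson(params.spont * pre_duration)
        out.append(schedule.blank_onset + rng.uniform(0, pre_duration, n_pre))
    # thinning ceiling: envelope terms are each bounded by 1
    ceiling = params.spont + params.direction_gain(direction, speed) * params.speed_gain(
        speed
    ) * (params.transient_gain(speed) + params.sustained_gain)
    ceiling = float(max(ceiling, 1e-12))
    duration = schedule.motion_duration
    n_cand = rng.poisson(ceiling * duration)
    if n_cand:
        t_cand = np.sort(rng.uniform(0, duration, n_cand))
        accept = rng.uniform(0, ceiling, n_cand) < rate_function(
            t_cand, direction, speed, params
        )
        out.append(schedule.motion_onset + t_cand[accept])
    if not out:
        return np.array([])
    return np.sort(np.concatenate(out))


def default_population_config() -> dict:
    """The versioned default population specification (shipped YAML)."""
    text = resources.files("lmspeed").joinpath("population_defaults.yaml").read_text()
    return yaml.safe_load(text)


def _largest_remainder(fractions: Dict[str, float], n: int) -> Dict[str, int]:
    keys = list(fractions)
    exact = np.array([fractions[k] * n for k in keys])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts.astype(int)))


def _draw_params(rng: np.random.Generator, archetype: str, cfg: dict) -> ArchetypeParams:
    p = cfg["cell_params"]
    spont = rng.uniform(*p["spont_range"])
    tn_frac = p.get("tn_fraction", 0.65)
    if archetype in ("directional", "dir_to_omni") and rng.uniform() < tn_frac:
        pd = rng.uniform(-22.5, 22.5) % 360.0  # temporal-to-nasal preferring
    else:
        pd = rng.uniform(0.0, 360.0)
    kappa0 = 0.0 if archetype == "omnidirectional" else rng.uniform(*p["kappa0_range"])
    peak_gain = 0.0 if archetype == "unmodulated" else p["gain_over_spont"] * spont
    kappa_decay = p["kappa_decay_dir_to_omni"] if archetype == "dir_to_omni" else 1.0
    centers = p["speed_center_choices"]
    return ArchetypeParams(
        archetype=archetype,
        pd=pd,
        kappa0=kappa0,
        kappa_decay=kappa_decay,
        speed_center=float(centers[rng.integers(len(centers))]),
        speed_sigma=rng.uniform(*p["speed_sigma_range"]),
        peak_gain=peak_gain,
        spont=spont,
        transient_gain_slope=rng.uniform(*p["transient_gain_slope_range"]),
        it_gain=rng.uniform(*p["it_gain_range"]),
        latency_base=rng.uniform(*p["latency_base_range"]),
        latency_slope=rng.uniform(*p["latency_slope_range"]),
    )


def generate_population(
    config: Optional[dict] = None, seed: int = 1
) -> Tuple[List[CellRecording], List[GroundTruth]]:
    """Generate a reproducible population matching the configured mix exactly.

    Archetype counts and the wide/dense protocol split follow the config
    fractions by largest-remainder rounding; per-cell parameters are drawn
    from stable per-cell streams keyed on (seed, cell index).
    """
    if config is None:
        config = default_population_config()
    mix: Dict[str, float] = dict(config["archetype_mix"])
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"archetype mix fractions sum to {total}, not 1")
    unknown = set(mix) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
    n_cells = int(config["n_cells"])
    counts = _largest_remainder(mix, n_cells)
    archetypes = [a for a in mix for _ in range(counts[a])]
    n_wide = int(round(config.get("wide_fraction", 0.42) * n_cells))
    n_sweeps = int(config.get("n_sweeps", 10))

    recordings, truths = [], []
    for i, archetype in enumerate(archetypes):
        rng = _cell_rng(seed, i)
        params = _draw_params(rng, archetype, config)
        protocol = get_protocol("wide" if i < n_wide else "dense")
        cell_id = f"syn{i:03d}"
        # offset the spike-stream index so parameter and spike draws decouple
        rec, truth = simulate_cell(
            params, protocol, n_sweeps=n_sweeps, seed=seed,
            cell_id=cell_id, cell_index=i + 1_000_000,
        )
        recordings.append(rec)
        truths.append(truth)
    return recordings, truths


def truth_table(truths: Sequence[GroundTruth]):
    """Tidy per-cell x speed ground-truth labels as a DataFrame."""
    import pandas as pd

    rows = []
    for t in truths:
        for speed, label in sorted(t.labels.items()):
            rows.append({
                "cell_id": t.cell_id,
                "archetype": t.archetype,
                "pd_true": t.pd,
                "speed": speed,
                "true_label": label,
            })
    return pd.DataFrame(rows)
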