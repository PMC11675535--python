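"""Two-stage classification of direction responses.

Stage 1 assigns each cell x speed response one of three tuning-curve shapes
(directional, bidirectional, omnidirectional), either by a deterministic
rule on the shape features or by a gradient-boosted tree model trained on
rule-labeled examples (mirroring manual labeling of most-active responses).
Stage 2 reclassifies a response as unmodulated when it is statistically
indistinguishable from the spontaneous rate: fewer than six directions
significantly different from baseline AND sensitivity index <= 0.29.

Stage 2 can only move labels toward unmodulated, never between shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .io import CellRecording
from .metrics import (
    DirectionResponse,
    ShapeFeatures,
    FEATURE_NAMES,
    direction_response,
    most_active_speed,
    shape_features,
    spontaneous_rate,
    spontaneous_replicates,
    epoch_rate,
)

__all__ = [
    "SHAPE_LABELS",
    "ALL_LABELS",
    "ClassifiedResponse",
    "InclusionResult",
    "Stage1Model",
    "inclusion_filter",
    "direction_significance",
    "rule_classifier",
    "stage1_train",
    "stage2_reclassify",
    "classify_cell",
    "classify_population",
    "classification_table",
]

SHAPE_LABELS = ("directional", "bidirectional", "omnidirectional")
ALL_LABELS = SHAPE_LABELS + ("unmodulated",)

# stage-2 rule constants
SI_UNMODULATED = 0.29  # inclusive boundary
MIN_SIGNIFICANT_DIRECTIONS = 6
INCLUSION_RATE = 5.0  # spikes/s above spontaneous
ICV_OMNIDIRECTIONAL = 3.0  # inverse CV at or above this marks a near-flat curve


@dataclass
class InclusionResult:
    included: bool
    reasons: List[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.included


@dataclass
class ClassifiedResponse:
    """Final label for one cell x speed response, with provenance."""

    cell_id: str
    speed: float
    label: str
    stage: int  # 1 = shape label retained, 2 = reclassified unmodulated
    n_significant_directions: int
    features: ShapeFeatures
    stage1_label: str = ""
    rule_label: str = ""


def inclusion_filter(
    cell: CellRecording, spont: Optional[float] = None
) -> InclusionResult:
    """Global-motion selectivity filter applied before any classification.

    A cell is kept when, at some speed, (a) at least one direction has a
    mean spontaneous-subtracted rate >= 5 spikes/s, and (b) at least one
    such condition is sustained: positive mean modulation in both the
    200-1,000 ms and the 1,000-3,000 ms windows of the motion epoch.
    """
    if spont is None:
        spont = spontaneous_rate(cell)
    strong = False
    sustained = False
    for speed in cell.speeds:
        resp = direction_response(cell, speed, spont=spont)
        for i, direction in enumerate(resp.directions):
            if resp.mean_rate[i] < INCLUSION_RATE:
                continue
            strong = True
            early, late = _sustain_windows(cell, speed, direction, spont)
            if early > 0 and late > 0:
                sustained = True
                break
        if sustained:
            break
    reasons = []
    if not strong:
        reasons.append("no direction with response >= 5 spikes/s above spontaneous")
    elif not sustained:
        reasons.append("no qualifying condition sustained beyond the onset transient")
    return InclusionResult(included=strong and sustained, reasons=reasons)


def _sustain_windows(cell, speed, direction, spont) -> Tuple[float, float]:
    early_rates, late_rates = [], []
    for trial, sp in cell.trials_at(speed, direction):
        on = trial.schedule.motion_onset
        early_rates.append(epoch_rate(sp, on + 0.2, on + 1.0) - spont)
        late_rates.append(epoch_rate(sp, on + 1.0, on + 3.0) - spont)
    return float(np.mean(early_rates)), float(np.mean(late_rates))


def direction_significance(
    resp: DirectionResponse,
    spont_replicates: np.ndarray,
    alpha: float = 0.05,
) -> int:
    """Directions whose per-sweep motion rates differ from baseline.

    Two-sided Wilcoxon rank-sum of the per-sweep motion-epoch rates (raw,
    i.e. with the baseline added back) against the per-trial
    spontaneous-window rates, at level ``alpha``, uncorrected.
    """
    spont_replicates = np.asarray(spont_replicates, dtype=float)
    count = 0
    for rates in resp.sweep_rates:
        raw = np.asarray(rates) + resp.spont
        if len(raw) < 3:
            import warnings

            warnings.warn(
                f"{resp.cell_id}: fewer than 3 sweeps at speed {resp.speed}; "
                "rank-sum test is unreliable",
                stacklevel=2,
            )
        stat, p = ranksums(raw, spont_replicates)
        if p < alpha:
            count += 1
    return count


def rule_classifier(features: ShapeFeatures) -> str:
    """Deterministic three-way shape rule (the canonical labeling oracle).

    directional: SI > 0.2 with at most one prominent peak, or with two
    peaks whose height ratio exceeds 2; omnidirectional: inverse CV >= 3
    (a near-flat curve -- its peaks are noise ripple, not bimodality) or
    anything left after the other rules, including flat curves flagged
    with infinite inverse CV; bidirectional: exactly two peaks, SI <= 0.2
    and substantial modulation relative to the curve mean (inverse CV < 3).
    """
    si = 0.0 if math.isnan(features.si) else features.si
    icv = features.inverse_cv
    near_flat = math.isnan(icv) or icv >= ICV_OMNIDIRECTIONAL
    if si > 0.2 and features.peak_count <= 1:
        return "directional"
    if si > 0.2 and features.peak_count == 2 and features.peak_ratio > 2.0:
        return "directional"
    if features.peak_count == 2 and si <= 0.2 and not near_flat:
        return "bidirectional"
    return "omnidirectional"


@dataclass
class Stage1Model:
    """A tuned boosted-tree shape classifier plus its training report."""

    booster: object  # xgboost.XGBClassifier
    classes: Tuple[str, ...]
    cv_accuracy: float
    train_accuracy: float
    best_params: Dict[str, object]
    feature_gain: Dict[str, float]
    feature_cover: Dict[str, float]

    def predict(self, features: Sequence[ShapeFeatures]) -> List[str]:
        X = np.vstack([f.as_array() for f in features])
        idx = self.booster.predict(X)
        return [self.classes[int(i)] for i in idx]

    def report(self) -> dict:
        return {
            "classes": list(self.classes),
            "cv_accuracy": self.cv_accuracy,
            "train_accuracy": self.train_accuracy,
            "best_params": {k: v for k, v in self.best_params.items()},
            "feature_gain": self.feature_gain,
            "feature_cover": self.feature_cover,
        }


def stage1_train(
    labeled: Sequence[Tuple[ShapeFeatures, str]],
    seed: int = 0,
    param_grid: Optional[Dict[str, list]] = None,
) -> Stage1Model:
    """Tune a gradient-boosted shape classifier by repeated 5x5-fold CV.

    Labels must be restricted to the three shape classes; unmodulated is
    never a stage-1 class.  The grid is deliberately small (learning rate,
    depth, rounds, subsampling) and fully seeded, so retraining with the
    same inputs reproduces the same model.
    """
    from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
    from xgboost import XGBClassifier

    feats, labels = zip(*labeled)
    bad = sorted(set(labels) - set(SHAPE_LABELS))
    if bad:
        raise ValueError(f"stage-1 labels must be among {SHAPE_LABELS}; got {bad}")
    X = np.vstack([f.as_array() for f in feats])
    classes = tuple(sorted(set(labels)))
    y = np.array([classes.index(l) for l in labels])

    if param_grid is None:
        param_grid = {
            "learning_rate": [0.1, 0.3],
            "max_depth": [2, 4],
            "n_estimators": [50, 150],
            "subsample": [0.8, 1.0],
        }
    base = XGBClassifier(
        objective="multi:softmax",
        num_class=len(classes),
        random_state=seed,
        n_jobs=1,
        tree_method="exact",
        verbosity=0,
    )
    cv = RepeatedStratifiedKFold(n_splits=5, n_repeats=5, random_state=seed)
    search = GridSearchCV(base, param_grid, cv=cv, scoring="accuracy", n_jobs=1)
    search.fit(X, y)
    model = search.best_estimator_
    train_acc = float(np.mean(model.predict(X) == y))

    booster = model.get_booster()
    booster.feature_names = list(FEATURE_NAMES)
    gain = booster.get_score(importance_type="gain")
    cover = booster.get_score(importance_type="cover")
    return Stage1Model(
        booster=model,
        classes=classes,
        cv_accuracy=float(search.best_score_),
        train_accuracy=train_acc,
        best_params=dict(search.best_params_),
        feature_gain={k: float(gain.get(k, 0.0)) for k in FEATURE_NAMES},
        feature_cover={k: float(cover.get(k, 0.0)) for k in FEATURE_NAMES},
    )


def stage2_reclassify(
    label: str,
    features: ShapeFeatures,
    n_significant: int,
    *,
    cell_id: str = "",
    speed: float = math.nan,
    si_threshold: float = SI_UNMODULATED,
    min_significant: int = MIN_SIGNIFICANT_DIRECTIONS,
) -> ClassifiedResponse:
    """Apply the unmodulated rule to a stage-1 shape label.

    The label becomes unmodulated iff fewer than ``min_significant``
    directions differ from baseline AND SI <= ``si_threshold`` (inclusive:
    a worked boundary case with SI exactly 0.29 is reclassified).
    """
    if not 0 <= n_significant <= 8:
        raise ValueError("n_significant must be in 0..8")
    si = 0.0 if math.isnan(features.si) else features.si
    if n_significant < min_significant and si <= si_threshold:
        return ClassifiedResponse(
            cell_id=cell_id, speed=speed, label="unmodulated", stage=2,
            n_significant_directions=n_significant, features=features,
            stage1_label=label,
        )
    return ClassifiedResponse(
        cell_id=cell_id, speed=speed, label=label, stage=1,
        n_significant_directions=n_significant, features=features,
        stage1_label=label,
    )


def classify_cell(
    cell: CellRecording,
    stage1_model: Optional[Stage1Model] = None,
    alpha: float = 0.05,
    motion_window=None,
) -> List[ClassifiedResponse]:
    """Classify every speed of one cell; records rule and model labels."""
    spont = spontaneous_rate(cell)
    spont_reps = spontaneous_replicates(cell)
    out = []
    for speed in cell.speeds:
        resp = direction_response(cell, speed, motion_window=motion_window, spont=spont)
        feats = shape_features(resp)
        rule_label = rule_classifier(feats)
        if stage1_model is not None:
            stage1_label = stage1_model.predict([feats])[0]
        else:
            stage1_label = rule_label
        n_sig = direction_significance(resp, spont_reps, alpha=alpha)
        classified = stage2_reclassify(
            stage1_label, feats, n_sig, cell_id=cell.cell_id, speed=speed
        )
        classified.rule_label = rule_label
        out.append(classified)
    return out


def build_training_set(
    cells: Sequence[CellRecording],
    n_extra: int = 100,
    seed: int = 0,
    motion_window=None,
) -> List[Tuple[ShapeFeatures, str]]:
    """Rule-labeled training examples mirroring manual labeling.

    One example per cell at its most-active speed, plus ``n_extra``
    randomly chosen additional modulated responses.
    """
    rng = np.random.default_rng(seed)
    labeled = []
    pool = []
    for cell in cells:
        spont = spontaneous_rate(cell)
        best = most_active_speed(cell, motion_window=motion_window, spont=spont)
        for speed in cell.speeds:
            resp = direction_response(cell, speed, motion_window=motion_window, spont=spont)
            feats = shape_features(resp)
            if speed == best:
                labeled.append((feats, rule_classifier(feats)))
            elif float(np.max(resp.mean_rate)) >= INCLUSION_RATE:
                pool.append(feats)
    if pool and n_extra:
        take = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
        for i in take:
            labeled.append((pool[i], rule_classifier(pool[i])))
    return labeled


def classify_population(
    cells: Sequence[CellRecording],
    stage1_model: Optional[Stage1Model] = None,
    alpha: float = 0.05,
    motion_window=None,
) -> List[ClassifiedResponse]:
    """One ClassifiedResponse per cell x tested speed, in input order."""
    out: List[ClassifiedResponse] = []
    for cell in cells:
        out.extend(
            classify_cell(cell, stage1_model=stage1_model, alpha=alpha,
                          motion_window=motion_window)
        )
    return out


def classification_table(classified: Sequence[ClassifiedResponse]) -> pd.DataFrame:
    """Tidy audit table of the full two-stage classification."""
    rows = []
    for c in classified:
        rows.append({
            "cell_id": c.cell_id,
            "speed": c.speed,
            "label": c.label,
            "stage": c.stage,
            "stage1_label": c.stage1_label,
            "rule_label": c.rule_label,
            "n_significant": c.n_significant_directions,
            "pd": c.features.pd,
            "si": c.features.si,
            "inverse_cv": c.features.inverse_cv,
            "ap_pd": c.features.ap_pd,
            "peak_count": c.features.peak_count,
        })
    return pd.DataFrame(rows)
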