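import math

import numpy as np
import pytest
from scipy.stats import norm

from lmspeed.classify import (
    ICV_OMNIDIRECTIONAL,
    build_training_set,
    classify_cell,
    direction_significance,
    inclusion_filter,
    rule_classifier,
    stage1_train,
    stage2_reclassify,
)
from lmspeed.io import DENSE_PROTOCOL
from lmspeed.metrics import DirectionResponse, ShapeFeatures
from lmspeed.synth import ArchetypeParams, simulate_cell

DIRS = np.arange(0.0, 360.0, 45.0)


def features(si=0.5, icv=1.0, ap=0.1, peaks=1, ratio=math.inf, pd=0.0):
    return ShapeFeatures(pd=pd, si=si, inverse_cv=icv, ap_pd=ap,
                         peak_count=peaks, peak_ratio=ratio)


def resp_from_sweeps(sweeps_by_direction, spont=0.0, speed=32.0):
    sweep_rates = [np.asarray(s, dtype=float) - spont for s in sweeps_by_direction]
    return DirectionResponse(
        cell_id="c", speed=speed, directions=DIRS.copy(),
        mean_rate=np.array([np.mean(s) for s in sweep_rates]),
        sweep_rates=sweep_rates, spont=spont,
        n_sweeps=np.array([len(s) for s in sweep_rates]),
    )


class TestInclusion:
    def test_silent_cell_excluded_for_weak_response(self, single_speed_protocol):
        p = ArchetypeParams(archetype="unmodulated", peak_gain=0.0, spont=2.0)
        cell, _ = simulate_cell(p, single_speed_protocol, n_sweeps=5, seed=1)
        result = inclusion_filter(cell)
        assert not result
        assert any("5 spikes/s" in r for r in result.reasons)

    def test_sustained_strong_cell_included(self, single_speed_protocol):
        p = ArchetypeParams(archetype="directional", pd=0.0)
        cell, _ = simulate_cell(p, single_speed_protocol, n_sweeps=5, seed=1)
        assert inclusion_filter(cell)

    def test_transient_only_cell_excluded_as_unsustained(self):
        # fires only during the first 150 ms of every motion epoch
        from lmspeed.io import CellRecording, EpochSchedule, Trial

        trials, spikes = [], []
        for d in DIRS:
            trials.append(Trial(trial_id=f"t{d}", direction=d,
                                spatial_frequency=0.25, temporal_frequency=8.0,
                                sweep_index=1, schedule=EpochSchedule()))
            spikes.append(np.linspace(2.0, 2.149, 30))  # 30 spikes, 10 sp/s overall
        cell = CellRecording(cell_id="transient", trials=trials, spikes=spikes)
        result = inclusion_filter(cell)
        assert not result
        assert any("sustained" in r for r in result.reasons)


class TestDirectionSignificance:
    def test_identical_rates_give_zero(self):
        sweeps = [[5.0] * 8 for _ in range(8)]
        resp = resp_from_sweeps(sweeps, spont=5.0)
        spont_reps = np.full(64, 5.0)
        assert direction_significance(resp, spont_reps) == 0

    def test_large_consistent_elevation_detected(self, rng):
        spont_reps = rng.poisson(5, 200) * 2.0  # 0.5 s windows at ~5 sp/s
        sweeps = [list(rng.poisson(5, 10)) for _ in range(7)]
        sweeps.append(list(rng.poisson(30, 10)))  # one strongly elevated direction
        resp = resp_from_sweeps([np.array(s, float) for s in sweeps], spont=5.0)
        assert direction_significance(resp, spont_reps) >= 1

    def test_matches_independent_ranksum_implementation(self, rng):
        """Count agrees exactly with a hand-rolled normal-approximation test."""
        spont_reps = rng.poisson(6, 150).astype(float)
        sweeps = [rng.poisson(rate, 10).astype(float)
                  for rate in (6, 6, 8, 12, 20, 12, 8, 6)]
        resp = resp_from_sweeps(sweeps, spont=6.0)

        def oracle_count(alpha=0.05):
            count = 0
            for raw in [s + 6.0 for s in resp.sweep_rates]:
                pooled = np.concatenate([raw, spont_reps])
                ranks = np.empty(len(pooled))
                order = np.argsort(pooled)
                # midranks for ties
                sorted_vals = pooled[order]
                i = 0
                while i < len(sorted_vals):
                    j = i
                    while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
                        j += 1
                    ranks[order[i:j + 1]] = (i + j) / 2 + 1
                    i = j + 1
                n1, n2 = len(raw), len(spont_reps)
                w = ranks[:n1].sum()
                mu = n1 * (n1 + n2 + 1) / 2
                sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
                p = 2 * norm.sf(abs((w - mu) / sd))
                if p < alpha:
                    count += 1
            return count

        assert direction_significance(resp, spont_reps) == oracle_count()

    def test_few_sweeps_warns(self):
        resp = resp_from_sweeps([[4.0, 5.0]] * 8, spont=5.0)
        with pytest.warns(UserWarning, match="fewer than 3 sweeps"):
            direction_significance(resp, np.full(20, 5.0))


class TestRuleClassifier:
    def test_sharp_single_peak_is_directional(self):
        assert rule_classifier(features(si=0.6, peaks=1)) == "directional"

    def test_two_balanced_peaks_low_si_is_bidirectional(self):
        assert rule_classifier(features(si=0.05, icv=0.9, peaks=2)) == "bidirectional"

    def test_flat_modulated_curve_is_omnidirectional(self):
        assert rule_classifier(features(si=0.05, icv=4.0, peaks=0)) == "omnidirectional"

    def test_two_peaks_with_dominant_peak_is_directional(self):
        assert rule_classifier(features(si=0.4, peaks=2, ratio=3.0)) == "directional"

    def test_near_flat_ripple_bimodality_is_omnidirectional(self):
        # two ripple peaks on an otherwise flat curve: inverse CV dominates
        f = features(si=0.05, icv=ICV_OMNIDIRECTIONAL + 5, peaks=2, ratio=1.2)
        assert rule_classifier(f) == "omnidirectional"

    def test_infinite_inverse_cv_is_omnidirectional(self):
        assert rule_classifier(features(si=0.0, icv=math.inf, peaks=0)) == "omnidirectional"


class TestStage2:
    def test_boundary_si_with_no_significant_directions_reclassified(self):
        out = stage2_reclassify("omnidirectional", features(si=0.29), 0)
        assert out.label == "unmodulated"
        assert out.stage == 2

    def test_six_significant_directions_keeps_directional(self):
        out = stage2_reclassify("directional", features(si=0.18), 6)
        assert out.label == "directional"
        assert out.stage == 1

    def test_high_si_keeps_stage1_label(self):
        out = stage2_reclassify("directional", features(si=0.50), 0)
        assert out.label == "directional"

    def test_reclassification_preserves_stage1_label_for_audit(self):
        out = stage2_reclassify("bidirectional", features(si=0.10), 2)
        assert out.label == "unmodulated"
        assert out.stage1_label == "bidirectional"

    def test_invalid_significant_count_rejected(self):
        with pytest.raises(ValueError):
            stage2_reclassify("directional", features(), 9)


def separable_training_set(n_per_class=40, seed=0):
    rng = np.random.default_rng(seed)
    labeled = []
    for _ in range(n_per_class):
        labeled.append((features(si=rng.uniform(0.5, 0.9), icv=rng.uniform(0.3, 1.0),
                                 peaks=1), "directional"))
        labeled.append((features(si=rng.uniform(0.0, 0.1), icv=rng.uniform(3.5, 8.0),
                                 peaks=0), "omnidirectional"))
        labeled.append((features(si=rng.uniform(0.0, 0.1), icv=rng.uniform(0.3, 1.0),
                                 peaks=2, ap=rng.uniform(0.8, 1.0)), "bidirectional"))
    return labeled


class TestStage1:
    def test_separable_features_reach_perfect_training_accuracy(self):
        model = stage1_train(separable_training_set(), seed=0)
        assert model.train_accuracy == 1.0

    def test_training_is_deterministic(self):
        m1 = stage1_train(separable_training_set(), seed=5)
        m2 = stage1_train(separable_training_set(), seed=5)
        assert m1.best_params == m2.best_params
        assert m1.cv_accuracy == m2.cv_accuracy
        assert m1.feature_gain == m2.feature_gain

    def test_unmodulated_label_rejected(self):
        labeled = separable_training_set(5) + [(features(), "unmodulated")]
        with pytest.raises(ValueError, match="unmodulated"):
            stage1_train(labeled, seed=0)

    def test_predictions_recover_training_labels(self):
        labeled = separable_training_set(20)
        model = stage1_train(labeled, seed=1)
        feats, labels = zip(*labeled)
        assert model.predict(list(feats)) == list(labels)


class TestClassifyCell:
    def test_archetypes_recovered_at_reference_speed(self, archetype_cells):
        for name, expected in [("directional", "directional"),
                               ("bidirectional", "bidirectional"),
                               ("omnidirectional", "omnidirectional")]:
            cell, _ = archetype_cells[name]
            out = {c.speed: c.label for c in classify_cell(cell)}
            assert out[32.0] == expected, name

    def test_dir_to_omni_transitions_with_speed(self, archetype_cells):
        cell, truth = archetype_cells["dir_to_omni"]
        out = {c.speed: c.label for c in classify_cell(cell)}
        assert out[32.0] == "directional"
        assert out[256.0] == "omnidirectional"

    def test_labels_invariant_to_trial_order(self, archetype_cells):
        from lmspeed.io import CellRecording

        cell, _ = archetype_cells["directional"]
        before = [(c.speed, c.label) for c in classify_cell(cell)]
        order = np.random.default_rng(0).permutation(len(cell.trials))
        shuffled = CellRecording(
            cell_id=cell.cell_id,
            trials=[cell.trials[i] for i in order],
            spikes=[cell.spikes[i] for i in order],
            protocol=cell.protocol,
        )
        after = [(c.speed, c.label) for c in classify_cell(shuffled)]
        assert before == after

    def test_stage2_only_moves_labels_to_unmodulated(self, pipeline_result):
        table = pipeline_result.tables["classification"]
        moved = table[table["stage"] == 2]
        assert (moved["label"] == "unmodulated").all()
        kept = table[table["stage"] == 1]
        assert (kept["label"] == kept["stage1_label"]).all()

    def test_training_set_mirrors_most_active_plus_extras(self, archetype_cells):
        cells = [rec for rec, _ in archetype_cells.values()]
        labeled = build_training_set(cells, n_extra=10, seed=0)
        assert len(labeled) >= len(cells)
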