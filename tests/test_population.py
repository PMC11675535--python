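import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lmspeed.metrics import DirectionResponse
from lmspeed.population import (
    CATEGORIES,
    across_speed_category,
    categorize_population,
    max_speed_proportions,
    normalize_directional,
    pd_stability,
    population_speed_curve,
    transition_counts,
)

DIRS = np.arange(0.0, 360.0, 45.0)
LABELS = ("directional", "bidirectional", "omnidirectional", "unmodulated")


def resp(rates, speed, cell_id="c"):
    rates = np.asarray(rates, dtype=float)
    return DirectionResponse(
        cell_id=cell_id, speed=speed, directions=DIRS.copy(), mean_rate=rates,
        sweep_rates=[np.array([r]) for r in rates], spont=0.0,
        n_sweeps=np.ones(8, dtype=int),
    )


class TestNormalization:
    def test_max_excitation_maps_to_plus_one(self):
        s = normalize_directional([resp([10, 5, 0, 0, 0, 0, 0, 0], 32.0)])
        assert s.r[32.0][0] == 1.0

    def test_spontaneous_level_maps_to_zero(self):
        s = normalize_directional([resp([10, 0, 0, 0, 0, 0, 0, 0], 32.0)])
        assert s.r[32.0][1] == 0.0

    def test_equal_magnitude_suppression_maps_to_minus_one(self):
        s = normalize_directional([resp([10, -10, 0, 0, 0, 0, 0, 0], 32.0)])
        assert s.r[32.0][1] == -1.0

    def test_idempotence(self):
        s1 = normalize_directional([resp([10, -4, 2, 0, 0, 0, 0, 0], 32.0)])
        again = [resp(s1.r[32.0], 32.0)]
        s2 = normalize_directional(again)
        np.testing.assert_allclose(s2.r[32.0], s1.r[32.0])
        assert s2.norm_constant == 1.0

    def test_all_zero_cell_flagged_flat(self):
        s = normalize_directional([resp([0.0] * 8, 32.0)])
        assert s.flat
        assert np.all(s.r[32.0] == 0.0)

    def test_extremum_is_plus_minus_one_for_non_silent_cells(self, rng):
        for _ in range(20):
            rates = rng.normal(0, 5, (3, 8))
            sets = normalize_directional(
                [resp(rates[i], s) for i, s in enumerate((4.0, 32.0, 256.0))]
            )
            peak = max(abs(v).max() for v in sets.r.values())
            assert peak == pytest.approx(1.0)


class TestSpeedCurve:
    def test_single_cell_curve_is_its_profile(self):
        sets = [normalize_directional(
            [resp([4, 0, 0, 0, 0, 0, 0, 0], 4.0), resp([8, 0, 0, 0, 0, 0, 0, 0], 32.0)]
        )]
        curve = population_speed_curve(sets)
        assert list(curve["mean_max_rn"]) == [0.5, 1.0]

    def test_duplicate_cell_leaves_mean_unchanged(self):
        one = normalize_directional(
            [resp([4, 0, 0, 0, 0, 0, 0, 0], 4.0), resp([8, 0, 0, 0, 0, 0, 0, 0], 32.0)]
        )
        single = population_speed_curve([one])
        doubled = population_speed_curve([one, one])
        np.testing.assert_allclose(single["mean_max_rn"], doubled["mean_max_rn"])

    def test_default_population_peaks_at_intermediate_speeds(self, pipeline_result):
        curve = pipeline_result.tables["speed_curve"]
        best = curve.loc[curve["mean_max_rn"].idxmax(), "speed"]
        assert best in (32.0, 64.0)


class TestMaxSpeedProportions:
    def test_counts_partition_population(self, pipeline_result):
        table = pipeline_result.tables["max_speed_proportions"]
        assert table["n_maximal"].sum() == 114
        assert ((table["proportion"] >= 0) & (table["proportion"] <= 1)).all()

    def test_modal_maximal_speed_is_32(self, pipeline_result):
        table = pipeline_result.tables["max_speed_proportions"]
        assert table.loc[table["n_maximal"].idxmax(), "speed"] == 32.0

    def test_all_cells_peaking_at_one_speed(self, archetype_cells):
        cell, _ = archetype_cells["directional"]
        table = max_speed_proportions([cell])
        assert table["n_maximal"].sum() == 1
        peak = table.loc[table["n_maximal"] == 1, "speed"].item()
        assert table.loc[table["speed"] == peak, "proportion"].item() == 1.0


class TestPdStability:
    def test_identical_pds_all_within_zone(self):
        pds = {4.0: 90.0, 32.0: 90.0, 256.0: 90.0}
        out = pd_stability(pds, 32.0)
        assert all(out.values())

    def test_boundary_is_inclusive(self):
        out = pd_stability({4.0: 112.5, 32.0: 90.0}, 32.0)
        assert out[4.0] is True

    def test_wraparound_distance(self):
        out = pd_stability({4.0: 350.0, 32.0: 10.0}, 32.0)
        assert out[4.0] is True

    def test_undefined_pd_flagged_none(self):
        out = pd_stability({4.0: math.nan, 32.0: 90.0}, 32.0)
        assert out[4.0] is None


class TestAcrossSpeedCategories:
    def test_directional_at_all_speeds_is_mostly_directional(self):
        labels = {s: "directional" for s in (4.0, 32.0, 256.0, 1024.0)}
        assert across_speed_category(labels).category == "mostly_directional"

    def test_directional_then_omni_is_dir_to_omni(self):
        labels = {4.0: "directional", 32.0: "directional",
                  256.0: "omnidirectional", 1024.0: "omnidirectional"}
        assert across_speed_category(labels).category == "dir_to_omni"

    def test_dir_to_omni_takes_precedence_over_mostly_directional(self):
        labels = {4.0: "directional", 32.0: "directional",
                  256.0: "omnidirectional", 1024.0: "directional"}
        assert across_speed_category(labels).category == "dir_to_omni"

    def test_bidirectional_at_32_is_variable(self):
        labels = {4.0: "unmodulated", 32.0: "bidirectional",
                  256.0: "omnidirectional", 1024.0: "directional"}
        assert across_speed_category(labels).category == "variable"

    def test_missing_speed_withholds_category(self):
        assert across_speed_category({32.0: "directional"}) is None

    def test_every_label_combination_gets_exactly_one_category(self):
        for combo in itertools.product(LABELS, repeat=4):
            labels = dict(zip((4.0, 32.0, 256.0, 1024.0), combo))
            cat = across_speed_category(labels)
            assert cat is not None
            assert cat.category in CATEGORIES

    def test_population_partition(self, pipeline_result):
        cats = pipeline_result.tables["categories"]
        assert len(cats) == 114
        assert cats["cell_id"].is_unique
        assert set(cats["category"]) <= set(CATEGORIES)


class TestTransitions:
    @staticmethod
    def label_table():
        rows = []
        for cid, labels in {
            "a": {32.0: "directional", 256.0: "omnidirectional"},
            "b": {32.0: "directional", 256.0: "directional"},
            "c": {32.0: "omnidirectional", 256.0: "omnidirectional"},
        }.items():
            rows += [{"cell_id": cid, "speed": s, "label": l} for s, l in labels.items()]
        return pd.DataFrame(rows)

    def test_cohort_of_one_is_a_single_unit_count(self):
        table = transition_counts(self.label_table(), 32.0, 256.0,
                                  cohort=lambda c: c == "a")
        assert table.to_numpy().sum() == 1
        assert table.loc["directional", "omnidirectional"] == 1

    def test_row_sums_conserve_cohort_size(self):
        table = transition_counts(self.label_table(), 32.0, 256.0)
        assert table.to_numpy().sum() == 3

    def test_chained_tables_conserve_cohort(self, pipeline_result):
        trans = pipeline_result.tables["tn_transitions"]
        cohort = pipeline_result.reports["tn_cohort"]["size"]
        for speed, group in trans.groupby("target_speed"):
            assert group["count"].sum() == cohort

    def test_fast_omni_cohort_mostly_directional_at_32(self, pipeline_result):
        labels = pipeline_result.tables["classification"]
        omni_at_fast = set(
            labels[(labels.speed == 1024.0) & (labels.label == "omnidirectional")].cell_id
        )
        table = transition_counts(labels, 32.0, 1024.0,
                                  cohort=omni_at_fast.__contains__)
        directional_row = table.loc["directional"].sum()
        assert directional_row > 0.5 * table.to_numpy().sum()
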