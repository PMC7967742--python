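"""Habitat degradation and quality: decay laws, oracle equivalence, grading."""

import numpy as np
import pandas as pd
import pytest

import habscape as h
from habscape import config_tables as ct
from habscape.quality import GRADE_NAMES


def _forest_map(shape=(16, 16), cell_size=30.0):
    return h.LandUseMap(np.full(shape, 3), cell_size=cell_size)


def _random_fixture(seed, shape=(24, 24)):
    rng = np.random.default_rng(seed)
    codes = rng.integers(1, 9, size=shape).astype(np.int32)
    lu = h.LandUseMap(codes, cell_size=100.0)
    specs = [
        ct.ThreatSpec("urban", 0.5, 1.0, "exponential"),
        ct.ThreatSpec("cultivated", 0.3, 0.5, "exponential"),
        ct.ThreatSpec("transportation", 0.4, 0.6, "linear"),
    ]
    sources = {
        "urban": codes == 5,
        "cultivated": codes == 1,
        "transportation": (codes == 5) & (rng.random(shape) < 0.3),
    }
    return lu, sources, specs


class TestDecay:
    @pytest.mark.parametrize("decay", ["linear", "exponential"])
    def test_unity_at_origin(self, decay):
        spec = ct.ThreatSpec("t", 3.0, 1.0, decay)
        assert h.decay_influence(0.0, spec) == 1.0

    def test_linear_zero_at_dmax(self):
        spec = ct.ThreatSpec("t", 3.0, 1.0, "linear")
        assert h.decay_influence(3000.0, spec) == 0.0
        assert h.decay_influence(4000.0, spec) == 0.0

    def test_exponential_value_at_dmax(self):
        spec = ct.ThreatSpec("t", 3.0, 1.0, "exponential")
        assert h.decay_influence(3000.0, spec) == pytest.approx(np.exp(-2.99))
        assert h.decay_influence(3000.1, spec) == 0.0  # truncated beyond

    def test_linear_halfway(self):
        spec = ct.ThreatSpec("t", 2.0, 1.0, "linear")
        assert h.decay_influence(1000.0, spec) == pytest.approx(0.5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            h.decay_influence(-1.0, ct.ThreatSpec("t", 1.0, 1.0, "linear"))


class TestThreatSources:
    def test_default_mapping_without_subtype(self):
        codes = np.array([[5, 1], [8, 6]])
        lu = h.LandUseMap(codes, cell_size=30)
        src = h.derive_threat_sources(lu)
        assert src["urban"][0, 0] and src["cultivated"][0, 1]
        assert src["saline_alkali"][1, 0]
        assert not src["rural_residential"].any()
        assert not src["transportation"].any()

    def test_subtype_splits_construction(self):
        codes = np.full((2, 2), 5)
        sub = np.array([[1, 2], [3, 4]])
        src = h.derive_threat_sources(h.LandUseMap(codes, cell_size=30), sub)
        for i, name in enumerate(
            ["urban", "rural_residential", "transportation", "mining"]
        ):
            assert src[name].sum() == 1

    def test_all_water_map_has_no_sources(self):
        lu = h.LandUseMap(np.full((4, 4), 6), cell_size=30)
        src = h.derive_threat_sources(lu)
        assert not any(s.any() for s in src.values())

    def test_unmapped_threat_rejected(self):
        lu = h.LandUseMap(np.full((2, 2), 6), cell_size=30)
        with pytest.raises(ValueError, match="mapping"):
            h.derive_threat_sources(lu, mapping={}, threat_names=["urban"])


class TestDegradation:
    def test_no_sources_zero(self):
        lu = _forest_map()
        sens = ct.load_sensitivity()
        D = h.degradation_index(
            {"urban": np.zeros(lu.shape, dtype=bool)},
            [ct.ThreatSpec("urban", 10, 1.0, "exponential")],
            sens,
            lu,
        )
        assert np.all(D.D == 0)

    def test_worked_single_source(self):
        """One linear threat, d_max = 2 cells: D = 0.5 one cell away."""
        lu, sources, specs, sens, _ = h.generate_quality_fixture("worked", (5, 5))
        D = h.degradation_index(sources, specs, sens, lu)
        assert D.D[0, 1] == pytest.approx(0.5)
        assert D.D[0, 0] == pytest.approx(1.0)  # the source cell itself
        assert D.D[0, 3] == pytest.approx(0.0)  # beyond d_max

    def test_insensitive_class_untouched(self):
        codes = np.full((9, 9), 8)  # unused: sensitivity to cultivated is 0
        codes[4, 4] = 1
        lu = h.LandUseMap(codes, cell_size=30)
        sens = ct.load_sensitivity()
        D = h.degradation_index(
            {"cultivated": codes == 1},
            [ct.ThreatSpec("cultivated", 1, 0.5, "exponential")],
            sens,
            lu,
        )
        assert np.all(D.D[codes == 8] == 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_convolution_matches_brute_force(self, seed):
        lu, sources, specs = _random_fixture(seed)
        sens = ct.load_sensitivity()
        fast = h.degradation_index(sources, specs, sens, lu)
        slow = h.degradation_brute_force(sources, specs, sens, lu)
        assert np.nanmax(np.abs(fast.D - slow.D)) <= 1e-6

    def test_accessibility_scales_linearly(self):
        lu, sources, specs = _random_fixture(9)
        sens = ct.load_sensitivity()
        beta = np.full(lu.shape, 0.25)
        full = h.degradation_index(sources, specs, sens, lu)
        scaled = h.degradation_index(sources, specs, sens, lu, beta)
        assert np.allclose(scaled.D, 0.25 * full.D)

    def test_zero_weight_sum_rejected(self):
        lu = _forest_map((4, 4))
        with pytest.raises(ValueError, match="zero"):
            h.degradation_index(
                {"urban": np.ones((4, 4), dtype=bool)},
                [ct.ThreatSpec("urban", 1, 0.0, "linear")],
                ct.load_sensitivity(),
                lu,
            )

    def test_scale_consistency(self):
        """Halving cell size at doubled resolution leaves D nearly unchanged."""
        sens = ct.load_sensitivity()
        spec = [ct.ThreatSpec("urban", 0.36, 1.0, "linear")]

        def build(cell, n):
            codes = np.full((n, n), 3)
            src = np.zeros((n, n), dtype=bool)
            src[0, 0] = True
            codes[0, 0] = 5
            lu = h.LandUseMap(codes, cell_size=cell)
            return h.degradation_index({"urban": src}, spec, sens, lu).D

        coarse = build(120.0, 8)
        fine = build(60.0, 16)
        # same metric location (268 m from the source, inside d_max = 360 m)
        assert coarse[2, 1] > 0
        assert abs(coarse[2, 1] - fine[4, 2]) <= 1e-3


class TestQuality:
    def test_zero_degradation_returns_habitat_score(self):
        sens = ct.load_sensitivity()
        for code, name in h.DEFAULT_CLASS_TABLE:
            lu = h.LandUseMap(np.full((3, 3), code), cell_size=30)
            D = h.DegradationMap(np.zeros((3, 3)), lu.nodata_mask)
            Q = h.quality_map(D, lu, sens)
            assert np.all(Q.Q == sens.habitat[name])

    def test_half_saturation_point(self):
        lu = _forest_map((2, 2))
        sens = ct.load_sensitivity()
        habitat = sens.habitat.copy()
        habitat["forest"] = 1.0
        sens1 = ct.SensitivityTable(habitat, sens.sensitivity)
        D = h.DegradationMap(np.full((2, 2), 0.5), lu.nodata_mask)
        Q = h.quality_map(D, lu, sens1, z=2.5, k=0.5)
        assert np.max(np.abs(Q.Q - 0.5)) <= 1e-12

    def test_construction_always_zero(self):
        lu = h.LandUseMap(np.full((3, 3), 5), cell_size=30)
        D = h.DegradationMap(np.random.default_rng(0).random((3, 3)), lu.nodata_mask)
        Q = h.quality_map(D, lu, ct.load_sensitivity())
        assert np.all(Q.Q == 0)

    def test_bounds(self):
        lu, sources, specs = _random_fixture(2)
        sens = ct.load_sensitivity()
        Q = h.quality_map(h.degradation_index(sources, specs, sens, lu), lu, sens)
        H = sens.habitat_array(lu.class_names)
        h_cell = H[np.searchsorted(lu.class_codes, lu.codes)]
        assert np.all(Q.Q >= 0) and np.all(Q.Q <= h_cell + 1e-12)

    def test_monotone_in_added_source(self):
        lu, sources, specs = _random_fixture(3)
        sens = ct.load_sensitivity()
        Q0 = h.quality_map(h.degradation_index(sources, specs, sens, lu), lu, sens)
        more = {k: v.copy() for k, v in sources.items()}
        free = np.argwhere(~more["urban"])
        more["urban"][tuple(free[0])] = True
        Q1 = h.quality_map(h.degradation_index(more, specs, sens, lu), lu, sens)
        assert np.all(Q1.Q <= Q0.Q + 1e-12)


class TestGrades:
    def test_bin_membership(self):
        vals = np.array([[0.05, 0.65], [0.4, 0.95]])
        Q = h.QualityMap(vals, np.zeros((2, 2), dtype=bool))
        grade, table = h.classify_grades(Q)
        named = dict(zip(GRADE_NAMES, range(5)))
        assert grade[0, 0] == named["Lower"]
        assert grade[0, 1] == named["High"]
        assert grade[1, 0] == named["Middle"]  # lower-inclusive at 0.4
        assert grade[1, 1] == named["Higher"]

    def test_proportions_sum_to_100(self):
        rng = np.random.default_rng(0)
        Q = h.QualityMap(rng.random((50, 50)), rng.random((50, 50)) < 0.1)
        _, table = h.classify_grades(Q)
        assert table["proportion_pct"].sum() == pytest.approx(100, abs=0.01)

    def test_non_monotone_bins_rejected(self):
        Q = h.QualityMap(np.zeros((2, 2)), np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            h.classify_grades(Q, bins=(0.4, 0.1))


class TestSummary:
    def test_constant_map(self):
        Q = h.QualityMap(np.full((4, 4), 0.9), np.zeros((4, 4), dtype=bool))
        s = h.summarize_quality(Q)
        assert s["mean"] == pytest.approx(0.9) and s["sd"] == 0

    def test_half_and_half_population_sd(self):
        vals = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = h.summarize_quality(h.QualityMap(vals, np.zeros((2, 2), dtype=bool)))
        assert s["mean"] == pytest.approx(0.5) and s["sd"] == pytest.approx(0.5)

    def test_empty_raster_rejected(self):
        Q = h.QualityMap(np.zeros((2, 2)), np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            h.summarize_quality(Q)


class TestFixtures:
    def test_no_threat_all_forest(self):
        _, _, _, _, expected = h.generate_quality_fixture("no_threat")
        assert np.all(expected.Q == 0.9)

    def test_all_construction_zero(self):
        _, _, _, _, expected = h.generate_quality_fixture("all_construction")
        assert np.all(expected.Q == 0)

    def test_single_threat_consistent_with_pipeline(self):
        lu, sources, specs, sens, expected = h.generate_quality_fixture(
            "single_threat"
        )
        Q = h.quality_map(
            h.degradation_index(sources, specs, sens, lu), lu, sens
        )
        assert np.nanmax(np.abs(Q.Q - expected.Q)) <= 1e-6
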