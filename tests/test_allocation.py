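"""CA competition: neighborhood effect, inertia, scoring, allocation, kappa."""

import numpy as np
import pytest

import habscape as h
from habscape.allocation import AllocationInfeasibleError


def _uniform_sp(lu):
    k = len(lu.class_codes)
    sp = np.full((k, *lu.shape), 1.0 / k)
    return h.SuitabilityStack(sp, lu.class_codes, lu.nodata_mask)


class TestNeighborhoodEffect:
    def test_full_window(self):
        lu = h.LandUseMap(np.full((3, 3), 5), cell_size=30)
        w = h.NeighborhoodWeights(np.array([0, 0, 0, 0, 1, 0, 0, 0.0]))
        assert h.neighborhood_effect(lu, 5, w)[1, 1] == 1.0

    def test_half_window_half_weight(self):
        codes = np.full((3, 3), 6)
        codes[0, 0] = codes[0, 2] = codes[2, 0] = codes[2, 2] = 1
        lu = h.LandUseMap(codes, cell_size=30)
        w = h.NeighborhoodWeights(np.array([0.5, 0, 0, 0, 0, 1, 0, 0.0]))
        assert h.neighborhood_effect(lu, 1, w)[1, 1] == pytest.approx(0.25)

    def test_absent_class_zero(self):
        lu = h.LandUseMap(np.full((3, 3), 6), cell_size=30)
        w = h.NeighborhoodWeights(np.ones(8))
        assert np.all(h.neighborhood_effect(lu, 1, w) == 0)

    def test_edges_keep_denominator(self):
        # corner cell has only 3 in-bounds neighbors; denominator stays 8
        lu = h.LandUseMap(np.full((3, 3), 6), cell_size=30)
        w = h.NeighborhoodWeights(np.array([0, 0, 0, 0, 0, 1, 0, 0.0]))
        assert h.neighborhood_effect(lu, 6, w)[0, 0] == pytest.approx(3 / 8)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            h.NeighborhoodWeights(np.ones(8), window=4)


class TestInertia:
    def _step(self, d2, d1, inertia=1.0):
        st = h.InertiaState(
            np.array([inertia]), D_prev1=np.array([d1]), D_prev2=np.array([d2])
        )
        return h.update_inertia(st).inertia[0]

    def test_shrinking_gap_unchanged(self):
        assert self._step(20, 10) == 1.0

    def test_under_allocation_worsening_boosts(self):
        assert self._step(10, 20) == pytest.approx(2.0)

    def test_over_allocation_worsening_damps(self):
        assert self._step(-20, -30) == pytest.approx(2 / 3)

    def test_zero_gap_guarded(self):
        assert self._step(0, 0) == 1.0
        assert self._step(0, 5) == 1.0  # |d1| > |d2| but signs break both cases

    def test_clamped(self):
        assert self._step(1e-9, 1e9, inertia=1.0) <= 1e3

    def test_first_iterations_keep_unity(self):
        st = h.InertiaState.initial(3)
        assert np.all(h.update_inertia(st).inertia == 1.0)


class TestCombinedProbability:
    def test_direct_product(self):
        lu = h.LandUseMap(np.full((2, 2), 8), cell_size=30)
        k = 8
        sp = h.SuitabilityStack(
            np.full((k, 2, 2), 0.5), lu.class_codes, lu.nodata_mask
        )
        omega = np.full((k, 2, 2), 0.25)
        allow = h.ConversionMatrix(np.ones((k, k), dtype=int), lu.class_codes)
        t = h.combined_probability(
            sp, omega, h.InertiaState.initial(k), allow, lu
        )
        assert np.allclose(t, 0.125)

    def test_forbidden_transition_scores_zero(self):
        lu = h.LandUseMap(np.full((2, 2), 3), cell_size=30)  # forest everywhere
        k = 8
        sp = h.SuitabilityStack(np.ones((k, 2, 2)), lu.class_codes, lu.nodata_mask)
        allow = np.ones((k, k), dtype=int)
        allow[2, 7] = 0  # forest -> unused forbidden
        t = h.combined_probability(
            sp,
            np.ones((k, 2, 2)),
            h.InertiaState.initial(k),
            h.ConversionMatrix(allow, lu.class_codes),
            lu,
        )
        assert np.all(t[7] == 0)
        assert np.all(t[2] == 1)  # self transition scored

    def test_all_unit_factors_give_one(self):
        lu = h.LandUseMap(np.full((2, 2), 1), cell_size=30)
        k = 8
        t = h.combined_probability(
            h.SuitabilityStack(np.ones((k, 2, 2)), lu.class_codes, lu.nodata_mask),
            np.ones((k, 2, 2)),
            h.InertiaState.initial(k),
            h.ConversionMatrix(np.ones((k, k), dtype=int), lu.class_codes),
            lu,
        )
        assert np.all(t == 1)


class TestRunAllocation:
    def _scenario(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        codes = rng.choice([1, 5, 6, 8], size=(n, n), p=[0.4, 0.2, 0.2, 0.2])
        lu = h.LandUseMap(codes.astype(np.int32), cell_size=30)
        allow = h.ConversionMatrix(np.ones((8, 8), dtype=int), lu.class_codes)
        weights = h.NeighborhoodWeights(np.full(8, 0.5))
        return lu, allow, weights

    def test_noop_when_demand_matches(self):
        lu, allow, weights = self._scenario()
        demand = h.DemandVector(lu.counts(), lu.class_codes)
        res = h.run_allocation(
            _uniform_sp(lu), lu, demand, allow=allow, weights=weights, seed=1, tol=0
        )
        assert np.array_equal(res.landuse.codes, lu.codes)
        assert res.converged and res.iterations == 0

    def test_demand_shift_satisfied(self):
        lu, allow, weights = self._scenario()
        counts = lu.counts()
        shift = counts[7] // 2  # unused -> cultivated
        demand = counts.copy()
        demand[7] -= shift
        demand[0] += shift
        res = h.run_allocation(
            _uniform_sp(lu),
            lu,
            h.DemandVector(demand, lu.class_codes),
            allow=allow,
            weights=weights,
            seed=1,
            tol=0,
        )
        assert res.converged
        assert np.array_equal(res.landuse.counts(), demand)

    def test_frozen_cells_never_change(self):
        lu, allow, weights = self._scenario()
        frozen = np.zeros(lu.shape, dtype=bool)
        frozen[:10] = True
        counts = lu.counts()
        demand = counts.copy()
        demand[7] -= counts[7] // 3
        demand[0] += counts[7] // 3
        res = h.run_allocation(
            _uniform_sp(lu),
            lu,
            h.DemandVector(demand, lu.class_codes),
            allow=allow,
            weights=weights,
            frozen=frozen,
            seed=1,
        )
        assert np.array_equal(res.landuse.codes[frozen], lu.codes[frozen])

    def test_forbidden_transitions_respected(self):
        lu, _, weights = self._scenario()
        allow_arr = np.ones((8, 8), dtype=int)
        allow_arr[7, :] = 0  # unused may not convert at all
        allow_arr[7, 7] = 1
        allow = h.ConversionMatrix(allow_arr, lu.class_codes)
        counts = lu.counts()
        demand = counts.copy()
        shift = counts[5] // 2  # take from water instead
        demand[5] -= shift
        demand[0] += shift
        res = h.run_allocation(
            _uniform_sp(lu),
            lu,
            h.DemandVector(demand, lu.class_codes),
            allow=allow,
            weights=weights,
            seed=1,
        )
        was_unused = lu.codes == 8
        assert np.array_equal(res.landuse.codes[was_unused], lu.codes[was_unused])

    def test_monotone_gap_trajectory(self):
        lu, allow, weights = self._scenario(seed=3)
        counts = lu.counts()
        demand = counts.copy()
        demand[7] -= counts[7] // 2
        demand[5] += counts[7] // 2
        res = h.run_allocation(
            _uniform_sp(lu),
            lu,
            h.DemandVector(demand, lu.class_codes),
            allow=allow,
            weights=weights,
            seed=2,
            tol=0,
        )
        assert all(a >= b for a, b in zip(res.trajectory, res.trajectory[1:]))

    def test_deterministic_given_seed(self):
        lu, allow, weights = self._scenario(seed=4)
        counts = lu.counts()
        demand = counts.copy()
        demand[7] -= 50
        demand[0] += 50
        kwargs = dict(allow=allow, weights=weights, seed=77, tol=0)
        r1 = h.run_allocation(
            _uniform_sp(lu), lu, h.DemandVector(demand, lu.class_codes), **kwargs
        )
        r2 = h.run_allocation(
            _uniform_sp(lu), lu, h.DemandVector(demand, lu.class_codes), **kwargs
        )
        assert np.array_equal(r1.landuse.codes, r2.landuse.codes)

    def test_all_frozen_with_demand_change_infeasible(self):
        lu, allow, weights = self._scenario()
        counts = lu.counts()
        demand = counts.copy()
        demand[0] += 10
        demand[7] -= 10
        with pytest.raises(AllocationInfeasibleError):
            h.run_allocation(
                _uniform_sp(lu),
                lu,
                h.DemandVector(demand, lu.class_codes),
                allow=allow,
                weights=weights,
                frozen=np.ones(lu.shape, dtype=bool),
                seed=0,
            )

    def test_unreachable_demand_diagnosed(self):
        lu, _, weights = self._scenario()
        allow_arr = np.eye(8, dtype=int)  # nothing may convert
        counts = lu.counts()
        demand = counts.copy()
        demand[0] += 20
        demand[7] -= 20
        with pytest.raises(AllocationInfeasibleError) as err:
            h.run_allocation(
                _uniform_sp(lu),
                lu,
                h.DemandVector(demand, lu.class_codes),
                allow=h.ConversionMatrix(allow_arr, lu.class_codes),
                weights=weights,
                seed=0,
            )
        assert err.value.diagnosis is not None
        assert not err.value.diagnosis["feasible"].all()


class TestValidateMap:
    def test_identical_maps_perfect(self, two_class_table):
        lu = h.LandUseMap(np.array([[1, 2], [2, 1]]), two_class_table, 30)
        rep = h.validate_map(lu, lu)
        assert rep.overall == 1.0 and rep.kappa == 1.0

    def test_worked_confusion_example(self, two_class_table):
        sim = np.array([1] * 45 + [2] * 5 + [1] * 5 + [2] * 45).reshape(10, 10)
        obs = np.array([1] * 50 + [2] * 50).reshape(10, 10)
        rep = h.validate_map(
            h.LandUseMap(sim, two_class_table, 30),
            h.LandUseMap(obs, two_class_table, 30),
        )
        assert rep.overall == pytest.approx(0.9)
        assert rep.kappa == pytest.approx(0.8)

    def test_hand_formula_agreement(self, two_class_table):
        """Kappa equals the marginal-products formula computed by hand."""
        rng = np.random.default_rng(0)
        sim = rng.choice([1, 2], size=(40, 40), p=[0.7, 0.3])
        obs = rng.choice([1, 2], size=(40, 40), p=[0.6, 0.4])
        rep = h.validate_map(
            h.LandUseMap(sim, two_class_table, 30),
            h.LandUseMap(obs, two_class_table, 30),
        )
        n = sim.size
        p_o = (sim == obs).mean()
        p_e = sum(
            (sim == c).sum() / n * (obs == c).sum() / n for c in (1, 2)
        )
        assert rep.kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_independent_maps_kappa_near_zero(self, two_class_table):
        rng = np.random.default_rng(1)
        sim = rng.choice([1, 2], size=(200, 200))
        obs = rng.choice([1, 2], size=(200, 200))
        rep = h.validate_map(
            h.LandUseMap(sim, two_class_table, 30),
            h.LandUseMap(obs, two_class_table, 30),
        )
        assert abs(rep.kappa) < 0.02

    def test_degenerate_constant_maps_undefined(self, two_class_table):
        lu = h.LandUseMap(np.full((4, 4), 1), two_class_table, 30)
        rep = h.validate_map(lu, lu.copy())
        assert np.isnan(rep.kappa)
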