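"""Kernel ratio estimation: adaptive bandwidths, kernel sums, adjustment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kremap as km
from kremap.kre import KernelSmoother

from conftest import uniform_pop
from oracles import naive_bandwidths, naive_kernel_sums


class TestBandwidths:
    def test_threshold_met_by_own_cell(self):
        pop = uniform_pop(6, 6, 250.0)
        bw = km.compute_bandwidths(pop, 250.0)
        np.testing.assert_array_equal(bw.radii, 0.0)

    def test_interior_radius_one_ring(self):
        # 100/cell, threshold 250: center + 4 rook neighbors = 500 >= 250,
        # reached at center distance = cell size
        pop = uniform_pop(9, 9, 100.0, cell_size=500.0)
        bw = km.compute_bandwidths(pop, 250.0)
        assert bw.radii[4, 4] == pytest.approx(500.0)

    def test_doubling_population_never_widens(self):
        rng = np.random.default_rng(8)
        spec = km.GridSpec(0, 0, 1000.0, 10, 10)
        counts = rng.uniform(5, 50, spec.shape)
        bw1 = km.compute_bandwidths(km.PopulationGrid(spec, counts), 250.0)
        bw2 = km.compute_bandwidths(km.PopulationGrid(spec, 2 * counts), 250.0)
        assert (bw2.radii <= bw1.radii).all()

    def test_insufficient_population_rejected(self):
        pop = uniform_pop(2, 2, 10.0)
        with pytest.raises(ValueError):
            km.compute_bandwidths(pop, 250.0)

    def test_minimality_per_cell(self):
        # dropping the farthest included distance ring leaves < threshold
        rng = np.random.default_rng(3)
        spec = km.GridSpec(0, 0, 1000.0, 7, 7)
        counts = rng.uniform(10, 80, spec.shape)
        pop = km.PopulationGrid(spec, counts)
        bw = km.compute_bandwidths(pop, 250.0)
        D = spec.pairwise_center_distances()
        flat = counts.ravel()
        for i in range(spec.n_cells):
            r = bw.radii.ravel()[i]
            inside = flat[D[i] <= r].sum()
            assert inside >= 250.0
            if r > 0:
                without_ring = flat[D[i] < r - 1e-9].sum()
                assert without_ring < 250.0


class TestKernelRatio:
    def test_proportional_cases_give_constant_ratio(self):
        rng = np.random.default_rng(1)
        spec = km.GridSpec(0, 0, 1000.0, 8, 8)
        counts = rng.uniform(20, 100, spec.shape)
        pop = km.PopulationGrid(spec, counts)
        bw = km.compute_bandwidths(pop, 250.0)
        k = 0.004
        surf = km.kernel_ratio(k * counts, pop, bw)
        np.testing.assert_allclose(surf.values, k, rtol=1e-12)

    def test_zero_cases_zero_ratio(self):
        pop = uniform_pop(5, 5, 100.0)
        bw = km.compute_bandwidths(pop, 250.0)
        surf = km.kernel_ratio(np.zeros((5, 5)), pop, bw)
        np.testing.assert_array_equal(surf.values, 0.0)

    def test_single_case_five_by_five(self):
        # uniform 100/cell, threshold 250 -> rook kernel of 5 cells (pop 500);
        # one case at the center: center ratio 1/500, cells whose kernel
        # misses the center see 0
        pop = uniform_pop(5, 5, 100.0)
        bw = km.compute_bandwidths(pop, 250.0)
        cases = np.zeros((5, 5)); cases[2, 2] = 1
        surf = km.kernel_ratio(cases, pop, bw)
        assert surf.values[2, 2] == pytest.approx(1 / 500)
        assert surf.values[0, 0] == 0.0

    def test_grid_mismatch_rejected(self):
        pop = uniform_pop(5, 5, 100.0)
        bw = km.compute_bandwidths(pop, 250.0)
        with pytest.raises(ValueError):
            km.kernel_ratio(np.zeros((4, 4)), pop, bw)

    @given(m=st.integers(min_value=1, max_value=20))
    def test_scale_covariance(self, m):
        rng = np.random.default_rng(2)
        spec = km.GridSpec(0, 0, 1000.0, 6, 6)
        pop = km.PopulationGrid(spec, rng.uniform(30, 90, spec.shape))
        bw = km.compute_bandwidths(pop, 200.0)
        cases = rng.integers(0, 5, spec.shape).astype(float)
        base = km.kernel_ratio(cases, pop, bw).values
        scaled = km.kernel_ratio(m * cases, pop, bw).values
        np.testing.assert_allclose(scaled, m * base, rtol=1e-12)

    def test_batched_ratio_matches_single(self):
        rng = np.random.default_rng(6)
        spec = km.GridSpec(0, 0, 1000.0, 6, 6)
        pop = km.PopulationGrid(spec, rng.uniform(30, 90, spec.shape))
        bw = km.compute_bandwidths(pop, 200.0)
        sm = KernelSmoother(pop, bw)
        stack = rng.integers(0, 5, (4,) + spec.shape).astype(float)
        batched = sm.ratio(stack)
        for i in range(4):
            np.testing.assert_array_equal(batched[i], sm.ratio(stack[i]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("shape,seed", [((12, 12), 0), ((20, 20), 1), ((7, 15), 2)])
    def test_vectorized_matches_naive(self, shape, seed):
        rng = np.random.default_rng(seed)
        spec = km.GridSpec(0, 0, 750.0, *shape)
        counts = rng.uniform(5, 120, shape)
        pop = km.PopulationGrid(spec, counts)
        bw = km.compute_bandwidths(pop, 250.0)
        np.testing.assert_allclose(
            bw.radii, naive_bandwidths(spec, counts, 250.0), rtol=1e-12
        )
        cases = rng.integers(0, 4, shape).astype(float)
        sm = KernelSmoother(pop, bw)
        np.testing.assert_allclose(
            sm.case_sums(cases).reshape(shape),
            naive_kernel_sums(spec, cases, bw.radii),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            sm.pop_sums.reshape(shape),
            naive_kernel_sums(spec, counts, bw.radii),
            rtol=1e-12,
        )


class TestDirectAdjust:
    def _surfaces(self, values_list, spec):
        return [km.RatioSurface(spec, v, label=f"a{i}") for i, v in enumerate(values_list)]

    def test_identical_surfaces_fixed_point(self):
        spec = km.GridSpec(0, 0, 1000.0, 3, 3)
        r = np.full((3, 3), 0.007)
        out = km.direct_adjust(self._surfaces([r, r, r], spec), [0.2, 0.5, 0.3])
        np.testing.assert_allclose(out.values, r)

    def test_degenerate_weights_select_stratum(self):
        spec = km.GridSpec(0, 0, 1000.0, 2, 2)
        a, b, c = (np.full((2, 2), v) for v in (0.1, 0.2, 0.3))
        out = km.direct_adjust(self._surfaces([a, b, c], spec), [1.0, 0.0, 0.0])
        np.testing.assert_allclose(out.values, a)

    def test_hand_arithmetic(self):
        spec = km.GridSpec(0, 0, 1000.0, 1, 1)
        surfaces = self._surfaces(
            [np.array([[0.002]]), np.array([[0.004]]), np.array([[0.006]])], spec
        )
        out = km.direct_adjust(surfaces, [0.5, 0.3, 0.2])
        assert out.values[0, 0] == pytest.approx(0.0034)

    def test_weight_count_mismatch(self):
        spec = km.GridSpec(0, 0, 1000.0, 1, 1)
        with pytest.raises(ValueError):
            km.direct_adjust(self._surfaces([np.ones((1, 1))], spec), [0.5, 0.5])

    def test_nodata_propagates(self):
        spec = km.GridSpec(0, 0, 1000.0, 1, 2)
        a = np.array([[0.1, np.nan]])
        b = np.array([[0.2, 0.2]])
        out = km.direct_adjust(self._surfaces([a, b], spec), [0.5, 0.5])
        assert np.isnan(out.values[0, 1]) and out.values[0, 0] == pytest.approx(0.15)

    def test_population_share_weights(self, small_region):
        _, groups, pop = small_region
        strata = km.stratify_population(pop, groups)
        w = km.population_share_weights(strata)
        assert w.sum() == pytest.approx(1.0)
        assert (w > 0).all()
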