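"""Hotspot delineation, apportionment, suppression, overlap algebra."""

import numpy as np
import pytest
import shapely
from hypothesis import given, strategies as st

import kremap as km
from kremap.hotspots import label_regions, apportion_cases, suppress, rate_in_out, overlap

from conftest import uniform_pop


SPEC = km.GridSpec(0, 0, 1000.0, 6, 6)  # 1 km2 cells


def _flags(cells):
    f = np.zeros(SPEC.shape, dtype=bool)
    for r, c in cells:
        f[r, c] = True
    return f


def _hotset(cells, cases=None, min_cases=11.0):
    hs = label_regions(_flags(cells), SPEC)
    if cases is not None:
        regions = hs.regions.copy()
        regions["cases"] = cases
        regions["late_cases"] = [v / 4 for v in cases]
        hs.regions = regions
        hs = suppress(hs, min_cases=min_cases)
    return hs


class TestLabeling:
    def test_no_flags_empty_set(self):
        hs = label_regions(np.zeros(SPEC.shape, dtype=bool), SPEC)
        assert hs.n_regions == 0
        assert not hs.unsuppressed_mask().any()

    def test_corner_touch_queen_vs_rook(self):
        cells = [(1, 1), (2, 2)]
        assert label_regions(_flags(cells), SPEC, connectivity=8).n_regions == 1
        assert label_regions(_flags(cells), SPEC, connectivity=4).n_regions == 2

    def test_area_is_cell_count_times_cell_area(self):
        hs = label_regions(_flags([(0, 0), (0, 1), (1, 0)]), SPEC)
        assert hs.n_regions == 1
        assert hs.regions["area_km2"].iloc[0] == pytest.approx(3.0)

    def test_labels_row_major_deterministic(self):
        hs = label_regions(_flags([(4, 4), (0, 5), (0, 0)]), SPEC)
        # region 1 must contain (0, 0), region 2 (0, 5), region 3 (4, 4)
        assert hs.labels[0, 0] == 1
        assert hs.labels[0, 5] == 2
        assert hs.labels[4, 4] == 3

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            label_regions(np.zeros(SPEC.shape, dtype=bool), SPEC, connectivity=6)


def _region_with_groups():
    """6x6 grid split into two 3-row block groups with known population."""
    polys = [shapely.box(0, 3000, 6000, 6000), shapely.box(0, 0, 6000, 3000)]
    groups = km.BlockGroupSet(
        ids=["top", "bottom"], polygons=polys,
        age_fractions=np.array([[1.0], [1.0]]), age_group_names=("all",),
    )
    pop = uniform_pop(6, 6, 10.0)
    return groups, pop


class TestApportionment:
    def test_full_block_group_coverage_gets_full_count(self):
        groups, pop = _region_with_groups()
        cells = [(r, c) for r in range(3) for c in range(6)]  # exactly "top"
        hs = label_regions(_flags(cells), SPEC)
        hs = apportion_cases(hs, groups, {"top": 40, "bottom": 12}, pop)
        assert hs.regions["cases"].iloc[0] == pytest.approx(40.0)
        assert hs.background_cases == pytest.approx(12.0)

    def test_half_population_half_count(self):
        groups, pop = _region_with_groups()
        cells = [(r, c) for r in range(3) for c in range(3)]  # half of "top"
        hs = label_regions(_flags(cells), SPEC)
        hs = apportion_cases(hs, groups, {"top": 40, "bottom": 12}, pop)
        assert hs.regions["cases"].iloc[0] == pytest.approx(20.0)

    def test_conservation_random(self, small_region):
        spec, groups, pop = small_region
        rng = np.random.default_rng(5)
        flags = rng.random(spec.shape) < 0.2
        counts = {gid: int(rng.integers(0, 30)) for gid in groups.ids}
        late = {gid: counts[gid] // 3 for gid in groups.ids}
        hs = label_regions(flags, spec)
        hs = apportion_cases(hs, groups, counts, pop, late_bg_counts=late)
        total = hs.regions["cases"].sum() + hs.background_cases
        assert total == pytest.approx(sum(counts.values()), rel=1e-9)
        total_late = hs.regions["late_cases"].sum() + hs.background_late_cases
        assert total_late == pytest.approx(sum(late.values()), rel=1e-9)

    def test_zero_population_group_warns_and_uses_cell_share(self):
        polys = [shapely.box(0, 3000, 6000, 6000), shapely.box(0, 0, 6000, 3000)]
        groups = km.BlockGroupSet(
            ids=["top", "bottom"], polygons=polys,
            age_fractions=np.array([[1.0], [1.0]]), age_group_names=("all",),
        )
        counts = np.zeros(SPEC.shape)
        counts[3:, :] = 10.0  # "top" has zero population
        pop = km.PopulationGrid(SPEC, counts)
        cells = [(r, c) for r in range(3) for c in range(3)]  # half of top's cells
        hs = label_regions(_flags(cells), SPEC)
        with pytest.warns(UserWarning, match="zero population"):
            hs = apportion_cases(hs, groups, {"top": 18, "bottom": 4}, pop)
        assert hs.regions["cases"].iloc[0] == pytest.approx(9.0)


class TestSuppression:
    def test_fractional_below_threshold_suppressed(self):
        hs = _hotset([(0, 0)], cases=[10.4])
        assert bool(hs.regions["suppressed"].iloc[0])

    def test_exactly_eleven_retained(self):
        hs = _hotset([(0, 0)], cases=[11.0])
        assert not bool(hs.regions["suppressed"].iloc[0])

    def test_all_large_unchanged(self):
        hs = _hotset([(0, 0), (3, 3)], cases=[30.0, 45.0])
        assert not hs.regions["suppressed"].any()
        assert hs.total_unsuppressed_area_km2() == pytest.approx(2.0)

    def test_monotone_in_threshold(self):
        base = _hotset([(0, 0), (3, 3)], cases=[12.0, 25.0])
        for lo, hi in [(5.0, 11.0), (11.0, 20.0), (20.0, 30.0)]:
            s_lo = suppress(base, min_cases=lo).regions["suppressed"]
            s_hi = suppress(base, min_cases=hi).regions["suppressed"]
            assert (s_lo <= s_hi).all()  # raising min_cases never un-suppresses

    def test_requires_apportioned_counts(self):
        hs = label_regions(_flags([(0, 0)]), SPEC)
        with pytest.raises(ValueError, match="apportion"):
            suppress(hs)

    def test_outcome_selects_count(self):
        hs = _hotset([(0, 0)], cases=[40.0])  # late = 10 < 11
        hs2 = suppress(hs, outcome="late_cases")
        assert bool(hs2.regions["suppressed"].iloc[0])


class TestRates:
    def test_single_region_rate(self):
        hs = _hotset([(0, 0)], cases=[20.0])
        hs.regions.loc[:, "late_cases"] = 5.0
        hs.background_cases, hs.background_late_cases = 100.0, 10.0
        rates = rate_in_out(hs)
        assert rates["in_hotspot_rate_region_avg"] == pytest.approx(0.25)
        assert rates["non_hotspot_rate"] == pytest.approx(0.10)

    def test_no_hotspots_non_hotspot_is_overall(self, small_region):
        spec, groups, pop = small_region
        hs = label_regions(np.zeros(spec.shape, dtype=bool), spec)
        hs = apportion_cases(hs, groups, {groups.ids[0]: 30}, pop,
                             late_bg_counts={groups.ids[0]: 6})
        rates = rate_in_out(hs)
        assert rates["non_hotspot_rate"] == pytest.approx(0.2)
        assert np.isnan(rates["in_hotspot_rate_region_avg"])

    def test_zero_case_region_rate_missing(self):
        hs = _hotset([(0, 0)], cases=[0.0], min_cases=0.0)
        hs.background_cases, hs.background_late_cases = 10.0, 1.0
        rates = rate_in_out(hs)
        assert np.isnan(rates["per_region_rate"].iloc[0])

    def test_uniform_late_probability_in_equals_out(self, study_region):
        # uniform late-stage probability p: in- and out-rates both ~ p
        spec, groups, pop = study_region
        scen = km.RiskScenario(baseline_rate=0.02, baseline_late_stage_probability=0.3,
                               unknown_stage_probability=0.0, seed=21)
        patients, _ = km.simulate_patients(pop, groups, scen)
        flags = np.zeros(spec.shape, dtype=bool)
        flags[10:20, 10:20] = True  # arbitrary region, risk is uniform
        from kremap.pipeline import _flatten_counts

        counts = _flatten_counts(km.block_group_counts(patients, groups, "incidence"))
        late = _flatten_counts(km.block_group_counts(patients, groups, "late_stage"))
        hs = label_regions(flags, spec)
        hs = apportion_cases(hs, groups, counts, pop, late_bg_counts=late)
        hs = suppress(hs, min_cases=11.0)
        rates = rate_in_out(hs)
        assert rates["in_hotspot_rate_pooled"] == pytest.approx(0.3, abs=0.05)
        assert rates["non_hotspot_rate"] == pytest.approx(0.3, abs=0.05)


class TestOverlap:
    def test_identical_sets(self):
        a = _hotset([(0, 0), (1, 1), (2, 2)], cases=[50.0])
        rep = overlap([a, a], names=["x", "y"])
        assert rep.pairwise_km2[("x", "y")] == pytest.approx(a.total_unsuppressed_area_km2())

    def test_disjoint_sets(self):
        a = _hotset([(0, 0)], cases=[50.0])
        b = _hotset([(5, 5)], cases=[50.0])
        rep = overlap([a, b])
        assert rep.pairwise_km2[("set1", "set2")] == 0.0

    def test_partial_overlap_by_hand(self):
        a = _hotset([(0, 0), (0, 1), (0, 2), (1, 0), (1, 1)], cases=[50.0])
        b = _hotset([(0, 0), (0, 1), (0, 2), (4, 4), (4, 5)], cases=[50.0, 50.0])
        empty = label_regions(np.zeros(SPEC.shape, dtype=bool), SPEC)
        rep = overlap([a, b, empty], names=["A", "B", "C"])
        assert rep.pairwise_km2[("A", "B")] == pytest.approx(3.0)
        assert rep.triple_km2 == 0.0

    def test_suppressed_regions_excluded(self):
        a = _hotset([(0, 0), (3, 3)], cases=[5.0, 50.0])  # first suppressed
        rep = overlap([a, a])
        assert rep.areas_km2["set1"] == pytest.approx(1.0)

    @given(seed=st.integers(min_value=0, max_value=500))
    def test_overlap_algebra(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for _ in range(3):
            flags = rng.random(SPEC.shape) < 0.3
            hs = label_regions(flags, SPEC)
            if hs.n_regions:
                hs.regions["cases"] = 100.0
                hs.regions["late_cases"] = 25.0
                hs = suppress(hs)
            sets.append(hs)
        rep = overlap(sets, names=["a", "b", "c"])
        rep_ba = overlap([sets[1], sets[0]], names=["b", "a"])
        # symmetry
        assert rep.pairwise_km2[("a", "b")] == rep_ba.pairwise_km2[("b", "a")]
        # min bound and triple bound
        for (x, y), v in rep.pairwise_km2.items():
            assert v <= min(rep.areas_km2[x], rep.areas_km2[y]) + 1e-12
            assert rep.triple_km2 <= v + 1e-12

    def test_grid_mismatch_rejected(self):
        a = _hotset([(0, 0)], cases=[50.0])
        other_spec = km.GridSpec(0, 0, 500.0, 6, 6)
        b = label_regions(np.zeros((6, 6), dtype=bool), other_spec)
        with pytest.raises(ValueError):
            overlap([a, b])

    def test_report_frame_shape(self):
        a = _hotset([(0, 0)], cases=[50.0])
        rep = overlap([a, a, a], names=["x", "y", "z"])
        df = rep.as_frame()
        assert len(df) == 3 + 3 + 1  # self areas, pairwise, triple
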