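"""Synthetic study region: block groups, gridded population, and patients.

The real analysis consumed a state cancer registry aggregated to Census
block groups plus a LandScan-style ambient-population raster.  This module
generates a self-contained analogue with known ground truth so every
downstream stage (disaggregation, kernel ratio estimation, significance,
hotspot delineation) is testable without restricted data:

* a contiguous tessellation of the grid into block-group polygons, each
  with a Dirichlet-drawn age-fraction vector;
* a heterogeneous (log-normal, optionally peaked) population raster;
* per-patient records drawn from a Poisson process whose intensity is
  ``population x baseline_rate x RR(cell)``, with circular planted
  high-risk zones, then aggregated back to block-group counts the way a
  registry would deliver them.

Cases live at cell-center resolution: the kernel estimator evaluates on
the raster and the population control is itself a raster, so sub-cell
coordinates would add no information.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.strtree import STRtree

from .grid import GridSpec, PopulationGrid

__all__ = [
    "BlockGroupSet",
    "DensityProfile",
    "PlantedZone",
    "RiskScenario",
    "generate_block_groups",
    "generate_population",
    "simulate_patients",
    "relative_risk_raster",
    "make_region",
]

DEFAULT_AGE_GROUPS = ("18-49", "50-64", "65+")
#: Dirichlet concentration for block-group age mixes: adult population
#: skews toward the younger screening-eligible strata.
DEFAULT_AGE_ALPHA = (5.0, 3.0, 2.0)


@dataclass
class BlockGroupSet:
    """A tessellation of the study region into block-group polygons.

    ``cell_labels`` maps each grid cell to the index of the block group
    containing its center; it is filled at generation time and recomputed
    by point-in-polygon when the set was read from GeoJSON.
    """

    ids: list[str]
    polygons: list[shapely.Polygon]
    age_fractions: np.ndarray  # (n_groups, n_age_groups), rows sum to 1
    age_group_names: tuple[str, ...] = DEFAULT_AGE_GROUPS
    cell_labels: Optional[np.ndarray] = None
    _label_spec: Optional[GridSpec] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.age_fractions = np.asarray(self.age_fractions, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("block group ids must be unique")
        if self.age_fractions.shape != (len(self.ids), len(self.age_group_names)):
            raise ValueError("age_fractions shape mismatch")
        sums = self.age_fractions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("each age_fractions row must sum to 1")

    @property
    def n_groups(self) -> int:
        return len(self.ids)

    @property
    def n_age_groups(self) -> int:
        return len(self.age_group_names)

    def labels_for(self, spec: GridSpec) -> np.ndarray:
        """Block-group index of each cell center; tessellation check.

        Raises if any cell center lies in no polygon or in more than one
        (the tessellation invariant).
        """
        if self.cell_labels is not None and self._label_spec == spec:
            return self.cell_labels
        pts = shapely.points(spec.flat_centers())
        tree = STRtree(self.polygons)
        pt_idx, poly_idx = tree.query(pts, predicate="covered_by")
        counts = np.bincount(pt_idx, minlength=len(pts))
        if np.any(counts == 0):
            raise ValueError("tessellation violated: cell center in no block group")
        labels = np.full(len(pts), -1, dtype=int)
        # keep the first covering polygon; >1 can only happen for a center
        # exactly on a shared boundary, which generated sets never produce
        for p, g in zip(pt_idx, poly_idx):
            if labels[p] < 0:
                labels[p] = g
        labels = labels.reshape(spec.shape)
        self.cell_labels = labels
        self._label_spec = spec
        return labels


@dataclass(frozen=True)
class DensityProfile:
    """Parameters of the synthetic ambient-population surface.

    mean_density
        Mean persons per cell.
    sigma_log
        Standard deviation of the log-normal multiplier (0 = uniform).
    peaks
        Optional urban peaks: (center_x, center_y, amplitude, width_m)
        Gaussian bumps multiplying the base density.
    """

    mean_density: float = 75.0
    sigma_log: float = 0.5
    peaks: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mean_density <= 0:
            raise ValueError("mean_density must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")


@dataclass(frozen=True)
class PlantedZone:
    """A circular zone of elevated (or depressed) relative risk."""

    center_x: float
    center_y: float
    radius_m: float
    relative_risk: float = 3.0
    late_stage_probability: Optional[float] = None  # None -> baseline

    def __post_init__(self) -> None:
        if self.relative_risk < 0:
            raise ValueError("relative_risk must be >= 0")
        if self.late_stage_probability is not None and not (
            0 <= self.late_stage_probability <= 1
        ):
            raise ValueError("late_stage_probability must be in [0, 1]")


@dataclass(frozen=True)
class RiskScenario:
    """Ground-truth generative model for patient records.

    ``baseline_rate`` is cases per person over the whole study window,
    either a scalar or one value per age stratum.
    """

    baseline_rate: float | tuple[float, ...] = 0.01
    planted_zones: tuple[PlantedZone, ...] = ()
    baseline_late_stage_probability: float = 0.15
    site: str = "breast"
    path_stage_observed_probability: float = 0.8
    unknown_stage_probability: float = 0.02
    missing_location_probability: float = 0.0
    seed: int = 0

    def rates(self, n_strata: int) -> np.ndarray:
        r = np.broadcast_to(np.asarray(self.baseline_rate, dtype=float), (n_strata,))
        if np.any(r < 0):
            raise ValueError("baseline_rate must be non-negative")
        if not 0 <= self.baseline_late_stage_probability <= 1:
            raise ValueError("late-stage probability must be in [0, 1]")
        return np.array(r)


def generate_block_groups(
    spec: GridSpec, n_groups: int, seed: int, age_alpha: Sequence[float] = DEFAULT_AGE_ALPHA
) -> BlockGroupSet:
    """Tessellate the grid extent into ``n_groups`` contiguous polygons.

    Regions are grown by seeded multi-source randomized flood fill from
    ``n_groups`` distinct cells, so every region is rook-connected and
    every cell belongs to exactly one region.  Age fractions are drawn
    from a Dirichlet with concentration ``age_alpha``.
    """
    if not 1 <= n_groups <= spec.n_cells:
        raise ValueError(
            f"n_groups must be in [1, {spec.n_cells}] for a {spec.n_rows}x{spec.n_cols} grid"
        )
    rng = np.random.default_rng(seed)
    n_rows, n_cols = spec.shape
    labels = np.full((n_rows, n_cols), -1, dtype=int)
    seeds = rng.choice(spec.n_cells, size=n_groups, replace=False)
    heap: list[tuple[float, int, int, int]] = []
    n_assigned = 0
    # claim seed cells first so no group can be starved by a neighbor
    for g, flat in enumerate(seeds):
        r, c = flat // n_cols, flat % n_cols
        labels[r, c] = g
        n_assigned += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and labels[rr, cc] < 0:
                heapq.heappush(heap, (rng.random(), rr, cc, g))
    while heap:
        _, r, c, g = heapq.heappop(heap)
        if labels[r, c] >= 0:
            continue
        labels[r, c] = g
        n_assigned += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and labels[rr, cc] < 0:
                heapq.heappush(heap, (rng.random(), rr, cc, g))
    assert n_assigned == spec.n_cells

    s = spec.cell_size
    polygons = []
    for g in range(n_groups):
        rows, cols = np.nonzero(labels == g)
        boxes = [
            box(
                spec.origin_x + c * s,
                spec.origin_y + (n_rows - r - 1) * s,
                spec.origin_x + (c + 1) * s,
                spec.origin_y + (n_rows - r) * s,
            )
            for r, c in zip(rows, cols)
        ]
        polygons.append(shapely.union_all(boxes))

    fractions = rng.dirichlet(np.asarray(age_alpha, dtype=float), size=n_groups)
    fractions = fractions / fractions.sum(axis=1, keepdims=True)
    ids = [f"BG{g:04d}" for g in range(n_groups)]
    names = tuple(DEFAULT_AGE_GROUPS) if len(age_alpha) == 3 else tuple(
        f"age{k}" for k in range(len(age_alpha))
    )
    return BlockGroupSet(
        ids=ids,
        polygons=polygons,
        age_fractions=fractions,
        age_group_names=names,
        cell_labels=labels,
        _label_spec=spec,
    )


def generate_population(
    spec: GridSpec,
    groups: BlockGroupSet,
    profile: DensityProfile = DensityProfile(),
    seed: int = 0,
) -> PopulationGrid:
    """Draw a heterogeneous ambient-population raster (LandScan analogue).

    Counts are ``mean_density`` times a unit-mean log-normal multiplier,
    further scaled by any urban peaks.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if profile.sigma_log > 0:
        mult = rng.lognormal(
            mean=-profile.sigma_log**2 / 2, sigma=profile.sigma_log, size=spec.shape
        )
    else:
        mult = np.ones(spec.shape)
    counts = profile.mean_density * mult
    if profile.peaks:
        xx, yy = spec.center_coords()
        for px, py, amp, width in profile.peaks:
            d2 = (xx - px) ** 2 + (yy - py) ** 2
            counts = counts * (1.0 + amp * np.exp(-d2 / (2 * width**2)))
    return PopulationGrid(spec, counts)


def relative_risk_raster(spec: GridSpec, zones: Sequence[PlantedZone]) -> np.ndarray:
    """True relative-risk surface: 1 outside zones, zone RR inside.

    A cell is inside a zone iff its center is within the zone radius;
    overlapping zones multiply.
    """
    rr = np.ones(spec.shape)
    xx, yy = spec.center_coords()
    for z in zones:
        inside = (xx - z.center_x) ** 2 + (yy - z.center_y) ** 2 <= z.radius_m**2
        rr[inside] *= z.relative_risk
    return rr


def _late_probability_raster(spec: GridSpec, scenario: RiskScenario) -> np.ndarray:
    p = np.full(spec.shape, scenario.baseline_late_stage_probability)
    xx, yy = spec.center_coords()
    for z in scenario.planted_zones:
        if z.late_stage_probability is not None:
            inside = (xx - z.center_x) ** 2 + (yy - z.center_y) ** 2 <= z.radius_m**2
            p[inside] = z.late_stage_probability
    return p


_EARLY_STAGES = np.array(["0", "I", "II"])
_EARLY_P = np.array([0.2, 0.5, 0.3])
_LATE_STAGES = np.array(["III", "IV"])
_LATE_P = np.array([0.5, 0.5])

_RACE_LEVELS = ["NH-White", "NH-Black", "NH-Other/Unknown", "Hispanic"]
_RACE_P = [0.88, 0.08, 0.02, 0.02]
_PAYER_LEVELS = ["Private", "Medicaid", "Medicare", "Uninsured/Self-Pay", "Other", "Unknown"]
_PAYER_P = [0.30, 0.05, 0.50, 0.03, 0.09, 0.03]
_RUCA_LEVELS = ["Metropolitan", "Micropolitan", "Small Town", "Rural"]
_RUCA_P = [0.75, 0.15, 0.06, 0.04]


def simulate_patients(
    pop: PopulationGrid,
    groups: BlockGroupSet,
    scenario: RiskScenario,
) -> tuple[pd.DataFrame, dict]:
    """Draw patient records from the ground-truth risk surface.

    Per age stratum ``a`` and cell ``c``, the case count is Poisson with
    mean ``pop_a(c) * rate_a * RR(c)`` where ``pop_a`` is the cell count
    scaled by its block group's age fraction.  Each case gets the block
    group containing its cell, a late/early stage with the cell's
    late-stage probability, and registry-style demographics.  Records are
    what a registry would deliver (block-group level); the returned
    ``truth`` dict carries the per-cell, per-stratum counts and the true
    RR raster for recovery scoring.

    Returns
    -------
    (patients, truth)
        ``patients`` is the record table; ``truth`` has keys
        ``cell_counts`` (n_strata, n_rows, n_cols), ``late_cell_counts``,
        ``rr_raster`` and ``late_probability``.
    """
    spec = pop.spec
    if pop.total <= 0:
        raise ValueError("population is empty")
    labels = groups.labels_for(spec)
    rng = np.random.default_rng(scenario.seed)
    n_strata = groups.n_age_groups
    rates = scenario.rates(n_strata)
    rr = relative_risk_raster(spec, scenario.planted_zones)
    p_late = _late_probability_raster(spec, scenario)

    frac_by_cell = groups.age_fractions[labels]  # (rows, cols, strata)
    records = []
    cell_counts = np.zeros((n_strata,) + spec.shape, dtype=int)
    late_counts = np.zeros_like(cell_counts)
    pid = 0
    for a, age_name in enumerate(groups.age_group_names):
        lam = pop.counts * frac_by_cell[..., a] * rates[a] * rr
        counts = rng.poisson(lam)
        cell_counts[a] = counts
        rows, cols = np.nonzero(counts)
        for r, c in zip(rows, cols):
            k = counts[r, c]
            late = rng.random(k) < p_late[r, c]
            late_counts[a, r, c] = int(late.sum())
            stages = np.where(
                late,
                rng.choice(_LATE_STAGES, size=k, p=_LATE_P),
                rng.choice(_EARLY_STAGES, size=k, p=_EARLY_P),
            )
            has_path = rng.random(k) < scenario.path_stage_observed_probability
            unknown = rng.random(k) < scenario.unknown_stage_probability
            missing_loc = rng.random(k) < scenario.missing_location_probability
            gid = groups.ids[labels[r, c]]
            for j in range(k):
                if unknown[j]:
                    path_stage, clin_stage = "unknown", "missing"
                elif has_path[j]:
                    path_stage, clin_stage = stages[j], "missing"
                else:
                    path_stage, clin_stage = "missing", stages[j]
                records.append(
                    {
                        "patient_id": f"P{pid:07d}",
                        "site": scenario.site,
                        "age_group": age_name,
                        "block_group_id": pd.NA if missing_loc[j] else gid,
                        "path_stage": path_stage,
                        "clin_stage": clin_stage,
                        "sex": "Female"
                        if scenario.site == "breast"
                        else ("Female" if rng.random() < 0.47 else "Male"),
                        "race_eth": rng.choice(_RACE_LEVELS, p=_RACE_P),
                        "payer": rng.choice(_PAYER_LEVELS, p=_PAYER_P),
                        "ruca": rng.choice(_RUCA_LEVELS, p=_RUCA_P),
                        "comorbidity_count": int(rng.poisson(0.6)),
                    }
                )
                pid += 1
    patients = pd.DataFrame.from_records(
        records,
        columns=[
            "patient_id", "site", "age_group", "block_group_id", "path_stage",
            "clin_stage", "sex", "race_eth", "payer", "ruca", "comorbidity_count",
        ],
    )
    patients["block_group_id"] = patients["block_group_id"].astype("string")
    truth = {
        "cell_counts": cell_counts,
        "late_cell_counts": late_counts,
        "rr_raster": rr,
        "late_probability": p_late,
    }
    return patients, truth


def make_region(
    n_rows: int = 40,
    n_cols: int = 40,
    cell_size: float = 1000.0,
    n_groups: int = 80,
    profile: DensityProfile = DensityProfile(),
    seed: int = 0,
) -> tuple[GridSpec, BlockGroupSet, PopulationGrid]:
    """One-call study region: grid spec, block groups, and population.

    Defaults give a 40 km x 40 km region of 1 km cells with 80 block
    groups of roughly 1,500 residents each — the scale at which a
    250-person adaptive kernel spans several cells per age stratum.
    """
    spec = GridSpec(0.0, 0.0, cell_size, n_rows, n_cols)
    seq = np.random.SeedSequence(seed)
    s_bg, s_pop = (int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(2))
    groups = generate_block_groups(spec, n_groups, seed=s_bg)
    pop = generate_population(spec, groups, profile, seed=s_pop)
    return spec, groups, pop
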