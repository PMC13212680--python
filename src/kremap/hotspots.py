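"""Hotspot delineation, case apportionment, suppression, and overlap.

Flagged cells are grouped into contiguous regions (queen/8-connectivity by
default).  Because patient counts exist only at the block-group level,
each region's case count is apportioned: a block group contributes its
count times the share of its population lying inside the region.  Regions
whose apportioned outcome-defining count falls below 11 cases are
suppressed for confidentiality and stability — apportioned counts are
fractional and compared to the threshold without rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .grid import GridSpec, PopulationGrid
from .synthetic import BlockGroupSet

__all__ = [
    "HotspotSet",
    "OverlapReport",
    "label_regions",
    "apportion_cases",
    "suppress",
    "rate_in_out",
    "overlap",
]


@dataclass
class HotspotSet:
    """Labeled contiguous significant regions on one GridSpec.

    ``labels`` is 0 for background and k >= 1 for region k; region ids are
    assigned in row-major order of each region's first cell, so labeling
    is deterministic.  ``regions`` carries one row per region:
    region_id, n_cells, area_km2, cases, late_cases, suppressed.
    """

    spec: GridSpec
    labels: np.ndarray
    regions: pd.DataFrame
    connectivity: int = 8
    background_cases: float = float("nan")
    background_late_cases: float = float("nan")
    outcome: str = "cases"

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def unsuppressed_mask(self) -> np.ndarray:
        """Boolean raster of cells in unsuppressed regions."""
        if self.n_regions == 0:
            return np.zeros(self.spec.shape, dtype=bool)
        if "suppressed" not in self.regions.columns or self.regions["suppressed"].isna().all():
            keep = set(self.regions["region_id"])
        else:
            keep = set(self.regions.loc[~self.regions["suppressed"].fillna(False), "region_id"])
        return np.isin(self.labels, list(keep)) & (self.labels > 0)

    def total_unsuppressed_area_km2(self) -> float:
        return float(self.unsuppressed_mask().sum()) * self.spec.cell_area_km2


def label_regions(
    flag: np.ndarray, spec: GridSpec, connectivity: int = 8
) -> HotspotSet:
    """Connected components of the flag raster, with per-region areas.

    ``connectivity`` is 4 (rook) or 8 (queen, default).  Labels are
    renumbered so that region k's first cell in row-major order precedes
    region k+1's.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    flag = np.asarray(flag, dtype=bool)
    if flag.shape != spec.shape:
        raise ValueError("flag raster does not match the grid")
    raw = measure.label(flag, connectivity=1 if connectivity == 4 else 2)
    labels = np.zeros_like(raw)
    order: list[int] = []
    for v in raw.ravel():
        if v > 0 and v not in order:
            order.append(v)
    for new_id, old in enumerate(order, start=1):
        labels[raw == old] = new_id
    rows = []
    for rid in range(1, len(order) + 1):
        n_cells = int((labels == rid).sum())
        rows.append(
            {
                "region_id": rid,
                "n_cells": n_cells,
                "area_km2": n_cells * spec.cell_area_km2,
                "cases": np.nan,
                "late_cases": np.nan,
                "suppressed": pd.NA,
            }
        )
    regions = pd.DataFrame(
        rows, columns=["region_id", "n_cells", "area_km2", "cases", "late_cases", "suppressed"]
    )
    return HotspotSet(spec=spec, labels=labels, regions=regions, connectivity=connectivity)


def _cell_weights(
    groups: BlockGroupSet, bg_counts: Mapping[str, float], pop: PopulationGrid
) -> np.ndarray:
    """Per-cell apportioned count: count(g) x cell population share of g.

    Block groups with zero population but a positive count fall back to
    equal shares over the group's cells, with a warning.
    """
    cell_labels = groups.labels_for(pop.spec)
    counts = np.array([float(bg_counts.get(gid, 0.0)) for gid in groups.ids])
    pop_flat = pop.counts.ravel()
    lab_flat = cell_labels.ravel()
    group_pop = np.bincount(lab_flat, weights=pop_flat, minlength=groups.n_groups)
    group_cells = np.bincount(lab_flat, minlength=groups.n_groups)
    share = np.zeros_like(pop_flat)
    ok = group_pop[lab_flat] > 0
    share[ok] = pop_flat[ok] / group_pop[lab_flat][ok]
    degenerate = (group_pop <= 0) & (counts > 0)
    if degenerate.any():
        bad = [groups.ids[g] for g in np.flatnonzero(degenerate)]
        warnings.warn(
            f"block groups with cases but zero population, apportioning by cell count: {bad}",
            stacklevel=2,
        )
    zero_pop_groups = group_pop <= 0
    fallback = zero_pop_groups[lab_flat]
    share[fallback] = 1.0 / group_cells[lab_flat][fallback]
    return (counts[lab_flat] * share).reshape(pop.spec.shape)


def apportion_cases(
    hotspots: HotspotSet,
    groups: BlockGroupSet,
    bg_counts: Mapping[str, float],
    pop: PopulationGrid,
    late_bg_counts: Optional[Mapping[str, float]] = None,
) -> HotspotSet:
    """Attribute block-group case counts to hotspot regions.

    Region r receives sum over block groups g of
    ``count(g) * population(g's cells inside r) / population(g)``; results
    stay fractional.  The remainder (background) is stored on the set so
    conservation can be checked: regions + background = total counts.
    """
    spec = hotspots.spec
    if pop.spec != spec:
        raise ValueError("population grid does not match the hotspot grid")
    w_cases = _cell_weights(groups, bg_counts, pop)
    w_late = _cell_weights(groups, late_bg_counts, pop) if late_bg_counts is not None else None
    regions = hotspots.regions.copy()
    for i, rid in enumerate(regions["region_id"]):
        mask = hotspots.labels == rid
        regions.loc[regions.index[i], "cases"] = float(w_cases[mask].sum())
        if w_late is not None:
            regions.loc[regions.index[i], "late_cases"] = float(w_late[mask].sum())
    outside = hotspots.labels == 0
    return HotspotSet(
        spec=spec,
        labels=hotspots.labels,
        regions=regions,
        connectivity=hotspots.connectivity,
        background_cases=float(w_cases[outside].sum()),
        background_late_cases=float(w_late[outside].sum()) if w_late is not None else float("nan"),
        outcome=hotspots.outcome,
    )


def suppress(
    hotspots: HotspotSet, min_cases: float = 11.0, outcome: str = "cases"
) -> HotspotSet:
    """Mark regions with fewer than ``min_cases`` apportioned cases.

    ``outcome`` selects the count the map reports ("cases" for incidence
    maps, "late_cases" for late-stage maps); a region with exactly
    ``min_cases`` is retained ("fewer than" is strict).
    """
    if outcome not in ("cases", "late_cases"):
        raise ValueError("outcome must be 'cases' or 'late_cases'")
    regions = hotspots.regions.copy()
    if len(regions) and regions[outcome].isna().any():
        raise ValueError("apportion counts before suppressing")
    regions["suppressed"] = regions[outcome] < min_cases
    return HotspotSet(
        spec=hotspots.spec,
        labels=hotspots.labels,
        regions=regions,
        connectivity=hotspots.connectivity,
        background_cases=hotspots.background_cases,
        background_late_cases=hotspots.background_late_cases,
        outcome=outcome,
    )


def rate_in_out(hotspots: HotspotSet, suppressed_included: bool = False) -> dict:
    """Late-stage proportions inside and outside hotspots.

    Per-region rate = late_cases / cases (NaN when a region has no
    cases).  The in-hotspot summary is reported two ways: the unweighted
    average across regions ("average proportion") and the case-weighted
    pooled rate.  The non-hotspot rate pools everything outside any
    region.  Suppressed regions are excluded unless requested.
    """
    regions = hotspots.regions
    if not suppressed_included and "suppressed" in regions.columns:
        regions = regions.loc[~regions["suppressed"].fillna(False)]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_region = (
            regions["late_cases"].to_numpy(dtype=float)
            / regions["cases"].to_numpy(dtype=float)
        )
    valid = ~np.isnan(per_region)
    total_cases = float(regions["cases"].sum())
    total_late = float(regions["late_cases"].sum())
    out_cases = hotspots.background_cases
    out_late = hotspots.background_late_cases
    return {
        "per_region_rate": pd.Series(per_region, index=regions["region_id"].to_numpy()),
        "in_hotspot_rate_region_avg": float(np.mean(per_region[valid])) if valid.any() else float("nan"),
        "in_hotspot_rate_pooled": total_late / total_cases if total_cases > 0 else float("nan"),
        "non_hotspot_rate": out_late / out_cases if out_cases and out_cases > 0 else float("nan"),
    }


@dataclass
class OverlapReport:
    """Pairwise (and triple) hotspot overlap areas in km² and % of region."""

    names: tuple[str, ...]
    areas_km2: dict[str, float]
    pairwise_km2: dict[tuple[str, str], float]
    triple_km2: Optional[float]
    region_area_km2: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"a": n, "b": n, "overlap_km2": self.areas_km2[n],
             "pct_of_region": 100.0 * self.areas_km2[n] / self.region_area_km2}
            for n in self.names
        ]
        for (a, b), v in self.pairwise_km2.items():
            rows.append({"a": a, "b": b, "overlap_km2": v,
                         "pct_of_region": 100.0 * v / self.region_area_km2})
        if self.triple_km2 is not None:
            rows.append({"a": "+".join(self.names), "b": "", "overlap_km2": self.triple_km2,
                         "pct_of_region": 100.0 * self.triple_km2 / self.region_area_km2})
        return pd.DataFrame(rows)


def overlap(hotspot_sets: Sequence[HotspotSet], names: Optional[Sequence[str]] = None) -> OverlapReport:
    """Intersection areas between 2 or 3 hotspot sets on a common grid.

    Suppressed regions are excluded.  Symmetric by construction; the
    triple intersection is reported when three sets are given.
    """
    if not 2 <= len(hotspot_sets) <= 3:
        raise ValueError("overlap takes 2 or 3 hotspot sets")
    spec = hotspot_sets[0].spec
    for hs in hotspot_sets[1:]:
        if hs.spec != spec:
            raise ValueError("hotspot sets share no GridSpec")
    if names is None:
        names = tuple(f"set{i+1}" for i in range(len(hotspot_sets)))
    names = tuple(names)
    cell = spec.cell_area_km2
    masks = [hs.unsuppressed_mask() for hs in hotspot_sets]
    areas = {n: float(m.sum()) * cell for n, m in zip(names, masks)}
    pairwise = {}
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            pairwise[(names[i], names[j])] = float((masks[i] & masks[j]).sum()) * cell
    triple = None
    if len(masks) == 3:
        triple = float((masks[0] & masks[1] & masks[2]).sum()) * cell
    return OverlapReport(
        names=names,
        areas_km2=areas,
        pairwise_km2=pairwise,
        triple_km2=triple,
        region_area_km2=spec.extent_area_km2,
    )
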