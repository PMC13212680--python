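"""Monte-Carlo point processes: age stratification, RCMC, and UCMC.

The registry delivers patient counts at the block-group level but the
kernel estimator needs locations at raster resolution.  Two multinomial
processes bridge the gap:

* **RCMC** (restricted, controlled): each block group's count is allocated
  over that block group's own cells with probabilities proportional to the
  cell's background population — the observed-data disaggregation.
* **UCMC** (unrestricted, controlled): the region-wide total is allocated
  over all cells proportional to population — the null model of no
  spatial variation in risk.

Both conserve totals exactly and place cases at cell centers.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Union

import numpy as np

from .grid import PopulationGrid
from .synthetic import BlockGroupSet

__all__ = ["stratify_population", "rcmc_disaggregate", "ucmc_simulate"]

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stratify_population(
    pop: PopulationGrid, groups: BlockGroupSet
) -> list[PopulationGrid]:
    """Split the ambient population into age strata by block-group mix.

    Every cell inherits the age structure of the block group containing
    its center: stratum ``a`` of cell ``c`` holds
    ``count(c) * age_fraction[group(c), a]``.  The strata partition each
    cell's count exactly (fractions sum to 1).
    """
    labels = groups.labels_for(pop.spec)
    frac = groups.age_fractions[labels]  # (rows, cols, strata)
    return [
        PopulationGrid(pop.spec, pop.counts * frac[..., a], stratum=name)
        for a, name in enumerate(groups.age_group_names)
    ]


def rcmc_disaggregate(
    bg_counts: Mapping[str, int],
    stratum_pop: PopulationGrid,
    groups: BlockGroupSet,
    seed: RngLike,
    zero_population_fallback: str = "uniform",
) -> np.ndarray:
    """Restricted controlled Monte-Carlo disaggregation of one stratum.

    For each block group independently, its count is multinomially
    allocated over the block group's cells with probabilities proportional
    to the stratum population of those cells.  Totals per block group are
    conserved exactly; no case can land outside its block group.

    A block group with a positive count but zero eligible population is a
    registry/population mismatch: by default its count is spread uniformly
    over its cells with a warning (``zero_population_fallback="uniform"``);
    set ``"error"`` to abort instead.

    Returns an integer case-count raster.
    """
    rng = _as_rng(seed)
    spec = stratum_pop.spec
    labels = groups.labels_for(spec)
    out = np.zeros(spec.shape, dtype=int)
    flat_pop = stratum_pop.counts.ravel()
    flat_labels = labels.ravel()
    flat_out = out.ravel()
    for g, gid in enumerate(groups.ids):
        count = int(bg_counts.get(gid, 0))
        if count == 0:
            continue
        cells = np.flatnonzero(flat_labels == g)
        weights = flat_pop[cells]
        total = weights.sum()
        if total <= 0:
            if zero_population_fallback == "error":
                raise ValueError(
                    f"block group {gid} has {count} cases but zero eligible population"
                )
            warnings.warn(
                f"block group {gid}: {count} cases but zero eligible population; "
                "allocating uniformly over its cells",
                stacklevel=2,
            )
            weights = np.ones_like(weights)
            total = weights.sum()
        flat_out[cells] += rng.multinomial(count, weights / total)
    return out


def ucmc_simulate(
    total_count: int, stratum_pop: PopulationGrid, seed: RngLike
) -> np.ndarray:
    """Unrestricted controlled Monte-Carlo null draw for one stratum.

    ``total_count`` cases are allocated multinomially over every cell of
    the region with probabilities proportional to the stratum population.
    """
    rng = _as_rng(seed)
    flat_pop = stratum_pop.counts.ravel()
    total = flat_pop.sum()
    if total <= 0:
        raise ValueError("stratum population is zero everywhere")
    if total_count < 0:
        raise ValueError("total_count must be non-negative")
    draw = rng.multinomial(int(total_count), flat_pop / total)
    return draw.reshape(stratum_pop.spec.shape)
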