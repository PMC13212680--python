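"""End-to-end hotspot detection: cohort -> RCMC -> KRE -> significance -> hotspots.

One call runs the full analytical chain for a site and outcome:

1. split the ambient population into age strata by block-group age mix;
2. aggregate patient records to per-stratum block-group counts
   (all cases for incidence maps, stage III/IV cases for late-stage maps);
3. per stratum, compute 250-person adaptive bandwidths from the stratum
   population and build the kernel smoother;
4. build the null ensemble: 199 UCMC draws -> KRE -> direct adjustment,
   smoothed with the identical bandwidths;
5. repeat RCMC disaggregation 10 times; each draw yields an adjusted
   observed surface and a per-cell Monte-Carlo p-value against the shared
   null ensemble;
6. flag cells where mean p + 2 sd < 0.01, label contiguous regions,
   apportion case and late-stage counts to regions by population share,
   and suppress regions with fewer than 11 outcome-defining cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .disaggregate import rcmc_disaggregate, stratify_population
from .grid import PopulationGrid
from .hotspots import HotspotSet, apportion_cases, label_regions, rate_in_out, suppress
from .kre import (
    BandwidthRaster,
    KernelSmoother,
    RatioSurface,
    compute_bandwidths,
    direct_adjust,
    population_share_weights,
)
from .significance import NullEnsemble, PValueSurface, aggregate_iterations, build_null_ensemble, mc_pvalue
from .synthetic import BlockGroupSet

__all__ = ["RunConfig", "DetectionResult", "detect_hotspots", "block_group_counts"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants; defaults are the published protocol's values.

    threshold_persons
        Adaptive-bandwidth person count (250).
    n_sims
        UCMC null simulations (199), giving a p-value floor of 0.005.
    n_rcmc
        RCMC disaggregation repeats (10).
    alpha
        Hotspot threshold on mean p + 2 sd (0.01).
    min_cases
        Suppression threshold: regions with fewer apportioned
        outcome-defining cases are withheld (11).
    connectivity
        Region contiguity, 4 (rook) or 8 (queen).
    bandwidth_population
        "stratum" (default) sizes each stratum's kernel by that stratum's
        own population; "total" uses the all-ages raster for every stratum.
    regenerate_null_per_iteration
        When True a fresh null ensemble is drawn for every RCMC iteration;
        the default shares one ensemble so iteration-to-iteration p
        variation isolates disaggregation uncertainty.
    """

    threshold_persons: float = 250.0
    n_sims: int = 199
    n_rcmc: int = 10
    alpha: float = 0.01
    min_cases: float = 11.0
    connectivity: int = 8
    bandwidth_population: str = "stratum"
    regenerate_null_per_iteration: bool = False
    detect_cold: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DetectionResult:
    """Everything the detection pipeline produced for one site x outcome."""

    config: RunConfig
    outcome: str
    pvalues: PValueSurface
    hotspots: HotspotSet
    observed_surfaces: list[RatioSurface]
    null_ensemble: NullEnsemble
    bandwidths: list[BandwidthRaster]
    weights: np.ndarray
    rates: dict
    cold_pvalues: Optional[PValueSurface] = None


def block_group_counts(
    patients: pd.DataFrame,
    groups: BlockGroupSet,
    outcome: str = "incidence",
) -> dict[str, dict[str, int]]:
    """Per-stratum block-group counts from patient records.

    ``outcome="incidence"`` counts every record; ``"late_stage"`` counts
    records whose resolved stage is III/IV.  Returns
    {age_group: {block_group_id: count}}.
    """
    if "late_stage" not in patients.columns:
        patients = cohort_mod.add_derived_columns(patients)
    if outcome == "late_stage":
        sub = patients[patients["late_stage"] == 1]
    elif outcome == "incidence":
        sub = patients
    else:
        raise ValueError("outcome must be 'incidence' or 'late_stage'")
    out: dict[str, dict[str, int]] = {a: {} for a in groups.age_group_names}
    grouped = sub.groupby(["age_group", "block_group_id"], observed=True).size()
    for (age, gid), n in grouped.items():
        if age not in out:
            raise ValueError(f"record age group {age!r} not among configured strata")
        out[age][str(gid)] = int(n)
    return out


def detect_hotspots(
    patients: pd.DataFrame,
    groups: BlockGroupSet,
    pop: PopulationGrid,
    outcome: str = "incidence",
    config: RunConfig = RunConfig(),
    weights: Optional[Sequence[float]] = None,
) -> DetectionResult:
    """Run the full detection chain for one site x outcome map."""
    spec = pop.spec
    patients = cohort_mod.add_derived_columns(patients)
    included, n_excluded = cohort_mod.apply_exclusions(patients)
    if n_excluded:
        logger.info("excluded %d records with missing block-group location", n_excluded)

    strata = stratify_population(pop, groups)
    if weights is None:
        weights = population_share_weights(strata)
    weights = np.asarray(weights, dtype=float)

    bw_source = strata if config.bandwidth_population == "stratum" else [pop] * len(strata)
    bandwidths = [compute_bandwidths(p, config.threshold_persons) for p in bw_source]
    smoothers = [KernelSmoother(p, b) for p, b in zip(strata, bandwidths)]
    logger.info(
        "bandwidths ready: %s",
        "; ".join(
            f"{s.stratum}: median {np.median(b.radii):.0f} m"
            for s, b in zip(strata, bandwidths)
        ),
    )

    counts = block_group_counts(included, groups, outcome=outcome)
    totals = [sum(counts[a].values()) for a in groups.age_group_names]
    logger.info("outcome=%s stratum totals=%s", outcome, totals)

    seq = np.random.SeedSequence(config.seed)
    null_seed, *iter_seeds = seq.spawn(1 + config.n_rcmc)
    null_rng = np.random.default_rng(null_seed)
    null = build_null_ensemble(
        strata, totals, bandwidths, weights,
        n_sims=config.n_sims, seed=null_rng, smoothers=smoothers,
    )

    observed_surfaces: list[RatioSurface] = []
    p_list: list[np.ndarray] = []
    p_cold_list: list[np.ndarray] = []
    for i in range(config.n_rcmc):
        rng = np.random.default_rng(iter_seeds[i])
        stratum_surfaces = []
        for a, age in enumerate(groups.age_group_names):
            cases = rcmc_disaggregate(counts[age], strata[a], groups, rng)
            stratum_surfaces.append(
                RatioSurface(spec, smoothers[a].ratio(cases), label=age, iteration=i)
            )
        adjusted = direct_adjust(stratum_surfaces, weights)
        adjusted.iteration = i
        observed_surfaces.append(adjusted)
        if config.regenerate_null_per_iteration and i > 0:
            null_i = build_null_ensemble(
                strata, totals, bandwidths, weights,
                n_sims=config.n_sims, seed=null_rng, smoothers=smoothers,
            )
        else:
            null_i = null
        p_list.append(mc_pvalue(adjusted, null_i))
        if config.detect_cold:
            low = RatioSurface(spec, -adjusted.values, label="adjusted", iteration=i)
            null_neg = NullEnsemble(spec, -null_i.values)
            p_cold_list.append(mc_pvalue(low, null_neg))

    pvals = aggregate_iterations(p_list, alpha=config.alpha, spec=spec)
    cold_pvals = (
        aggregate_iterations(p_cold_list, alpha=config.alpha, spec=spec)
        if config.detect_cold
        else None
    )
    hs = label_regions(pvals.flag, spec, connectivity=config.connectivity)

    all_counts = _flatten_counts(block_group_counts(included, groups, "incidence"))
    late_counts = _flatten_counts(block_group_counts(included, groups, "late_stage"))
    hs = apportion_cases(hs, groups, all_counts, pop, late_bg_counts=late_counts)
    outcome_col = "late_cases" if outcome == "late_stage" else "cases"
    hs = suppress(hs, min_cases=config.min_cases, outcome=outcome_col)
    n_sup = int(hs.regions["suppressed"].sum()) if hs.n_regions else 0
    logger.info(
        "outcome=%s: %d regions, %d suppressed, unsuppressed area %.1f km2",
        outcome, hs.n_regions, n_sup, hs.total_unsuppressed_area_km2(),
    )
    rates = rate_in_out(hs) if hs.n_regions else {
        "per_region_rate": pd.Series(dtype=float),
        "in_hotspot_rate_region_avg": float("nan"),
        "in_hotspot_rate_pooled": float("nan"),
        "non_hotspot_rate": (
            hs.background_late_cases / hs.background_cases
            if hs.background_cases > 0 else float("nan")
        ),
    }
    return DetectionResult(
        config=config,
        outcome=outcome,
        pvalues=pvals,
        hotspots=hs,
        observed_surfaces=observed_surfaces,
        null_ensemble=null,
        bandwidths=bandwidths,
        weights=weights,
        rates=rates,
        cold_pvalues=cold_pvals,
    )


def _flatten_counts(per_stratum: dict[str, dict[str, int]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for counts in per_stratum.values():
        for gid, n in counts.items():
            out[gid] = out.get(gid, 0.0) + n
    return out
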