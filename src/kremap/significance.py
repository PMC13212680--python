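"""Monte-Carlo significance of the observed ratio surface.

The null is an ensemble of age-adjusted ratio surfaces built from UCMC
draws (population-proportional allocation with no spatial risk structure),
smoothed with the *same* adaptive bandwidths as the observed data.  The
per-cell p-value for one disaggregation iteration is the rank of the
observed ratio within the null ensemble:

    p(c) = (1 + #{null ratios at c >= observed ratio at c}) / (n_sims + 1)

a valid one-sided Monte-Carlo p (the observed surface counts among the
ranks, so p is never 0 and its floor is 1/(n_sims+1) — 0.005 with the
default 199 simulations).  Disaggregation uncertainty is carried by
repeating RCMC: a cell is hot when the mean of its per-iteration p-values
plus two standard deviations is below alpha (0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import GridSpec, PopulationGrid
from .kre import BandwidthRaster, KernelSmoother, RatioSurface

__all__ = [
    "NullEnsemble",
    "PValueSurface",
    "build_null_ensemble",
    "mc_pvalue",
    "aggregate_iterations",
]


@dataclass
class NullEnsemble:
    """``n_sims`` age-adjusted null ratio surfaces on one GridSpec."""

    spec: GridSpec
    values: np.ndarray  # (n_sims, n_rows, n_cols)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.spec.shape:
            raise ValueError("ensemble values must be (n_sims, n_rows, n_cols)")
        if self.values.shape[0] < 1:
            raise ValueError("n_sims must be >= 1")

    @property
    def n_sims(self) -> int:
        return self.values.shape[0]


@dataclass
class PValueSurface:
    """Per-iteration p-values, their mean/sd, and the hotspot flag."""

    spec: GridSpec
    p_iters: np.ndarray  # (n_iters, n_rows, n_cols)
    mean_p: np.ndarray
    sd_p: np.ndarray
    flag: np.ndarray  # boolean
    alpha: float = 0.01


def build_null_ensemble(
    stratum_pops: Sequence[PopulationGrid],
    stratum_totals: Sequence[int],
    bandwidths: Sequence[BandwidthRaster],
    weights: Sequence[float],
    n_sims: int = 199,
    seed: int | np.random.Generator = 0,
    smoothers: Optional[Sequence[KernelSmoother]] = None,
) -> NullEnsemble:
    """UCMC -> KRE -> direct adjustment, ``n_sims`` times.

    Each simulation draws every stratum's observed total over the whole
    region proportional to that stratum's population, smooths with the
    stratum's own bandwidth raster, and directly adjusts across strata.
    Pass prebuilt ``smoothers`` to avoid rebuilding kernel matrices.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if smoothers is None:
        smoothers = [KernelSmoother(p, b) for p, b in zip(stratum_pops, bandwidths)]
    weights = np.asarray(weights, dtype=float)
    spec = stratum_pops[0].spec
    adjusted = np.zeros((n_sims,) + spec.shape)
    for a, (pop, sm) in enumerate(zip(stratum_pops, smoothers)):
        flat_pop = pop.counts.ravel()
        probs = flat_pop / flat_pop.sum()
        draws = rng.multinomial(int(stratum_totals[a]), probs, size=n_sims)
        ratios = sm.ratio(draws.reshape((n_sims,) + spec.shape))
        adjusted += weights[a] * ratios
    return NullEnsemble(spec, adjusted,
                        seed=None if isinstance(seed, np.random.Generator) else int(seed))


def mc_pvalue(observed: RatioSurface, null: NullEnsemble) -> np.ndarray:
    """One-sided per-cell Monte-Carlo p-value (high ratio = hot).

    Ties count toward the null (>=), so a surface identical to every null
    draw gets p = 1.  Cells that are nodata in the observed surface get
    NaN.
    """
    if null.spec != observed.spec:
        raise ValueError("observed surface and null ensemble share no GridSpec")
    obs = observed.values
    n_ge = np.sum(null.values >= obs[None, ...], axis=0)
    p = (1.0 + n_ge) / (null.n_sims + 1.0)
    return np.where(np.isnan(obs), np.nan, p)


def aggregate_iterations(
    p_surfaces: Sequence[np.ndarray], alpha: float = 0.01, spec: Optional[GridSpec] = None
) -> PValueSurface:
    """Combine per-iteration p-values into the hotspot flag.

    flag(c) = mean_p(c) + 2 * sd_p(c) < alpha, with the sample (n-1)
    standard deviation across disaggregation iterations.  Needs at least
    two iterations for the sd to exist; cells with any NaN p are never
    flagged.
    """
    arrs = [np.asarray(p, dtype=float) for p in p_surfaces]
    if len(arrs) < 2:
        raise ValueError("at least 2 iteration p-surfaces required")
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError("iteration p-surfaces have mismatched shapes")
    stack = np.stack(arrs)
    mean_p = stack.mean(axis=0)
    sd_p = stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        flag = (mean_p + 2.0 * sd_p) < alpha
    flag = np.where(np.isnan(mean_p) | np.isnan(sd_p), False, flag)
    return PValueSurface(
        spec=spec,  # type: ignore[arg-type]
        p_iters=stack,
        mean_p=mean_p,
        sd_p=sd_p,
        flag=flag.astype(bool),
        alpha=alpha,
    )
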