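# Methods

## The estimand and the analysis chain

`kremap` maps hotspots of disease incidence and late-stage diagnosis from
registry data delivered at the Census block-group level, against a gridded
ambient-population background (a LandScan-style raster). The local disease
intensity at a raster cell *c* is the **kernel ratio**

    r(c) = (cases within radius h(c) of c) / (population within h(c) of c)

with a **person-count adaptive bandwidth**: h(c) is the smallest
cell-center distance at which the cumulative background population around
*c* reaches a threshold (default 250 persons). Sparse rural cells get wide,
stable kernels; dense urban cells stay spatially sharp. Kernel weights are
uniform (top-hat) within the radius: the protocol describes a circular
neighborhood and a ratio of counts, and specifies no decay function, so the
uniform kernel is the minimal faithful reading. Distances are Euclidean
between cell centers in projected metres; a cell belongs to a kernel iff
its center is within the radius, inclusive, so all cells tied at the
critical distance are included and removing the outermost ring always drops
the kernel population below the threshold.

Because the kernel needs point-level cases but the registry delivers
block-group counts, two multinomial Monte-Carlo processes bridge the gap:

* **RCMC** (restricted, controlled): each block group's count is allocated
  over its own cells with probabilities proportional to the cell's
  background population. This is the observed-data disaggregation; it is
  repeated `n_rcmc` (default 10) times to carry disaggregation uncertainty.
* **UCMC** (unrestricted, controlled): the region-wide total is allocated
  over all cells proportional to population — the null model of no spatial
  risk variation. `n_sims` (default 199) draws form the null ensemble.

Cases are placed at cell centers, not continuous coordinates: the
population control and the kernel evaluation are both rasters, so sub-cell
jitter would add no information. Multinomial allocation (rather than
sequential or rejection sampling) gives exactly the population-proportional
weighting, conserves totals exactly, and vectorizes.

Age confounding is handled by **direct adjustment**: the population raster
is split into age strata by assuming every cell shares its block group's
age structure, KRE runs per stratum, and stratum surfaces are combined as a
weighted average. The standard weights default to the study region's own
stratum population shares (internal standardization); no external standard
population is imposed, and the weights are configurable.

Significance is Monte-Carlo: for each RCMC iteration,

    p(c) = (1 + #{null surfaces with ratio(c) >= observed ratio(c)}) / (n_sims + 1)

one-sided (high ratio = hot), with the observed surface counted among the
ranks so p is a valid Monte-Carlo p-value, never 0, with floor
1/(n_sims+1). Ties count toward the null. A cell is **flagged** when

    mean(p_1..p_k) + 2 * sd(p_1..p_k) < alpha      (alpha = 0.01)

across the k RCMC iterations, with the sample (n−1) standard deviation.
Note the floor arithmetic: at n_sims = 199 the floor is 0.005 < 0.01, so
flagging is attainable; at n_sims = 99 the floor equals the threshold and
nothing can ever be flagged — calibration runs at 99 simulations are
structurally zero-flag.

Flagged cells are grouped into contiguous regions (8-connectivity/queen by
default; 4 available). Case and late-stage counts are **apportioned** to a
region by population share: block group *g* contributes
`count(g) x pop(g ∩ region) / pop(g)`, kept fractional. Regions with fewer
than 11 apportioned outcome-defining cases (incident cases for incidence
maps, late-stage cases for late-stage maps) are **suppressed**; the
comparison is strict (`< 11`) and unrounded, which is deterministic and
conservative. Overlap between hotspot sets is computed on unsuppressed
cells only, in km² and as a share of the grid-extent area.

## Design choices where the protocol was open

* **Null comparison is adjusted-to-adjusted**: observed adjusted surfaces
  are ranked within an ensemble of adjusted null surfaces, keeping both
  pipelines symmetric (per-stratum-then-adjust on both sides).
* **One shared null ensemble across RCMC iterations** (regenerable per
  iteration by config): with the null fixed, iteration-to-iteration p
  variation isolates disaggregation uncertainty, which is what the
  mean+2sd rule is meant to absorb.
* **Bandwidths come from the stratum's own population** and the identical
  bandwidth raster is reused for observed and null surfaces of that
  stratum (`bandwidth_population="total"` switches to all-ages radii).
* **Late-stage denominators**: records whose resolved stage is unknown
  stay in the cohort for incidence but enter neither the late-stage
  numerator nor denominator.
* **In-hotspot late-stage summary** is reported both as the unweighted
  average across regions and as the case-weighted pooled rate; the
  region-averaged number is the headline ("average proportion").
* **Zero-population degeneracies** warn and fall back rather than abort: a
  block group with cases but no eligible population allocates uniformly
  over its cells (RCMC) or apportions by cell-count share (hotspot
  accounting); both are configurable to hard errors.
* Cold-spot detection (significantly low ratios) exists behind
  `RunConfig(detect_cold=True)` and is off by default.

## The synthetic study region

No public analogue of a statewide registry + LandScan pairing exists, so
the generator builds one with known ground truth:

* **Grid**: 40 x 40 cells of 1 km (1,600 km²). Cell size is fully
  configurable; nothing in the method depends on it beyond units.
* **Block groups**: 80 contiguous polygons grown by seeded multi-source
  random flood fill, ≈ 20 cells each. With the population below this makes
  ≈ 1,500 residents per block group, the right order for a Census block
  group (600–3,000).
* **Population**: mean 75 persons/cell with unit-mean log-normal
  multipliers (σ = 0.5), optional Gaussian urban peaks. At 75/cell a
  250-person stratum kernel spans several cells, so adaptive smoothing is
  actually exercised (at ≥ 250/cell every radius would be 0).
* **Age structure**: three strata (default labels 18–49, 50–64, 65+,
  matching screening-guideline age bands), Dirichlet(5, 3, 2) mixes per
  block group.
* **Cases**: independent Poisson per cell and stratum with mean
  `pop_a(c) x rate_a x RR(c)`; RR is 1 outside planted circular zones.
  The default `baseline_rate` = 0.01 cases/person over the study window
  (~1% cumulative incidence, the order of a decade of a common cancer).
  Stage: late with the cell's late-stage probability (baseline 0.15;
  planted zones may override), split III/IV 50:50; early split 0/I/II
  20:50:30. Pathologic stage observed with probability 0.8 (else clinical
  carries it); 2% of records are unknown-stage; demographics are drawn
  from fixed registry-like category frequencies.
* **Delivery**: records are aggregated back to block-group counts, which
  is all the detection pipeline sees; the per-cell truth (counts and RR
  raster) is exported separately for scoring.

What the generator does **not** emulate: real geography and spatially
structured covariates (deprivation, access), residential history,
registry coding error, within-block-group population micro-structure
beyond the raster, and correlation between incidence and late-stage risk
surfaces. Passing recovery tests therefore show the chain detects planted
multiplicative risk under its own generative assumptions — not that it
would resolve the messier confounding structure of real registry data.

## Test and calibration problem sizes

Calibration and recovery suites run on the 40 x 40 region with
`n_sims ∈ {99, 199}`, `n_rcmc = 5`, 20 replicate seeds each; brute-force
oracle comparisons use grids up to 20 x 20 at 1e-12 relative tolerance.
The planted-zone recovery scenario uses one RR = 3 zone of radius 5 km and
`baseline_rate` = 0.02. That rate is a power choice, fixed a priori by
kernel arithmetic: the baseline expected case count in a 250-person
stratum kernel is `250 x rate`; for the RR = 3 excess to clear the maximum
of 199 null draws consistently across disaggregation iterations — and for
the flagged region to accumulate more than the 11 apportioned cases the
suppression rule demands — that count needs to be ≈ 5, i.e. a rate of
0.02 (~2,400 cases). At the default 0.01 the zone is still flagged but the
unsuppressed-recovery rate drops to ~80%, driven by suppression of
fragmented sub-11-case regions, which is informative about the
suppression rule rather than about the estimator.

## Numerical notes

* Bandwidths and kernels are built from a dense pairwise center-distance
  matrix with a stable argsort; kernel membership (`d <= radius`) reuses
  the same distances, so tie handling is exact, and the membership matrix
  is cached sparse (CSR) — one matmul evaluates a whole null ensemble.
  Memory is O(n_cells²): fine to ~5,000 cells, beyond which a tiled
  implementation would be needed.
* Ratio cells with zero kernel population are NaN (nodata, −1 in ESRI
  ASCII output); NaN propagates through adjustment and is never flagged.
* All randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence.spawn`, so every stage is reproducible from one run seed
  and RCMC iteration index.
* Region labels are assigned in row-major order of each region's first
  cell, making labelings deterministic across runs and platforms.

## Known limitations

Only residence at diagnosis is modeled (no residential history); p-values
carry no multiple-testing correction across cells beyond the stringent
mean+2sd rule; the ratio surface is not an age-adjusted incidence *rate*
(the kernel ratio is a relative intensity, which is why hotspot output
reports proportions and areas rather than rates); reprojection is out of
scope — all inputs must share one grid.
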