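# Methods

## Signal model and Fourier decomposition

Each pixel's input is a multi-year stack of N seasonal NDVI composites
(default N = 11 16-day composites spanning Julian days 113–273, the high
fire-occurrence season; 13 years). Years are averaged composite-wise into a
single mean seasonal profile; a pixel is retained only if every composite
index has at least `min_years_valid` unmasked years (default ⌈n_years/2⌉ —
the input imagery is assumed pre-screened for quality, so residual gaps are
expected to be sparse).

Temporal Fourier analysis of the mean profile keeps the additive term A0
(series mean) and the amplitudes A1, A2 of the first two harmonics; phases
are discarded. Normalisation is fixed at 1/N for A0 and 2/N for the
harmonic coefficients, so a cosine of unit amplitude at the first harmonic
frequency yields A1 = 1 exactly. Any fixed affine rescaling of (A0, A1, A2)
leaves the downstream segmentation and clustering topology unchanged; it
only changes what a given numeric scale parameter means. Harmonics above
order 2, gap-filling and outlier rejection (HANTS-style smoothing) are out
of scope.

## Segmentation

The (A0, A1, A2) image is segmented by bottom-up pairwise region merging.
The merge cost is

    cost = (1 − w_shape) · Δh_colour + w_shape · Δh_shape

with Δh_colour = Σ_b w_b [n_m·sd_m,b − (n₁·sd₁,b + n₂·sd₂,b)] (population
standard deviations from running sum / sum-of-squares, variance clamped at
zero against rounding), and Δh_shape a compactness/smoothness blend using
n·l/√n (perimeter over square-root area, area-weighted) and n·l/b
(perimeter over bounding-box perimeter). A merge is accepted while
cost < scale². The total cost is clamped at zero: merging two fragments into
a more compact whole can lower the raw shape term, and a negative cost has
no meaning as a heterogeneity increase.

Merging proceeds by local mutual best fitting with a deterministic
ascending-id visiting order: a region merges with its cheapest neighbour
only if the choice is mutual, ties break toward the lower id, and passes
repeat until stable. This replaces the proprietary distributed treatment
order of commercial implementations; bit-compatibility with them is
explicitly not a goal, reproducibility is. Adjacency and perimeter use
4-connectivity (8-connectivity available; diagonal neighbours then share no
perimeter). Nodata pixels are excluded from the merge graph, so units never
span nodata gaps. A cleanup pass absorbs units below `min_pixels` (default
25) into the neighbour with the smallest colour cost, shape ignored.

Defaults (scale 500, shape 0.2, compactness 0.8, 25 px) are the operational
values for 250 m imagery whose Fourier bands carry raw-NDVI-scale units; on
synthetic test scenes the scale is chosen relative to the scene's band
contrast (block contrasts of ~0.1–0.3 NDVI give cross-block colour costs of
order 10²–10³ on a 40×40 scene, so scales of 0.5–5 recover the blocks).
Parameter selection on real imagery is inherently visual/iterative; all
three parameters are plain config values.

## Clustering

Units are represented by the arithmetic means of A0, A1, A2 over member
pixels and clustered by UPGMA on Euclidean distances (scipy's average
linkage). Features are not standardised by default — the three components
share NDVI units and their relative magnitudes are part of the signal — but
a `standardize` flag enables z-scoring. Cutting the tree at k removes the
k−1 highest merges; classes are labelled PFC1..PFCk by descending mean A1 of
their member units, so PFC1 is always the most seasonal class rather than an
arbitrary cluster index. Automatic selection of k is out of scope.

The optional split of the largest class into subgroups `a`/`b` is a spatial
surrogate for an expert-knowledge subdivision: 2-means on unit centroids
(50 restarts, fixed seed), with `a` assigned to the subgroup whose centroids
lie closer on average to the convex-hull boundary of all unit centroids — a
coastal-proximity proxy on island-shaped scenes. It is a documented
approximation: it reproduces *a* geographically coherent split, not any
particular expert's.

## Fire statistics

Ignition points are assigned to pixels via the inverse geotransform with
half-open pixel intervals, so edge points are deterministic; points outside
the extent or on nodata are excluded and counted. The selection ratio
σ_c = (n_c/N)/(a_c/A) is tested against the null of area-proportional
ignition by reallocating all N fires multinomially with probabilities a_c/A
(default 9999 replicates). Two-tailed Monte Carlo p-values double the
smaller tail with add-one continuity, min(1, 2·(min tail + 1)/(R + 1)); a
`tail="single"` flag reports the undoubled smaller tail instead. By
construction the area-weighted mean of σ is exactly 1 whenever every fire is
assigned.

The permutational ANOVA computes the classical one-way F on per-unit σ and
permutes unit labels (one-tailed, add-one rule); units are unweighted by
area. Zero within-group variance with non-zero between-group variance
reports F = ∞ and the minimum attainable p. Pairwise class comparisons rerun
the same test per unordered pair with independent seeds spawned from the
caller's seed, and carry no multiplicity adjustment (they are presented as
a-posteriori descriptives). Pairs with fewer than 3 units are flagged
not-testable.

Association with categorical covariates permutes the per-fire covariate
label vector, which fixes both margins of every randomized contingency
table exactly; the table-wide p is the upper tail of the permuted Pearson
χ² and cell-wise p-values use the same doubled-tail rule, with the cell's
direction read off against the null mean. Expected counts use the usual
row·col/total independence form; zero-margin rows/columns are dropped from
χ². The default land-cover schema is the seven combustible macro-classes
(urban, arable, permanent crops, heterogeneous agricultural, forests,
grasslands/pastures, shrublands); non-combustible surfaces are excluded
upstream.

## Synthetic scenes

The generator builds landscapes from class specs with known (base level,
amp1, amp2, phases, fire multiplier, covariate label). The seasonal signal
places its two cosines exactly at the first two DFT frequencies of the
composite grid, so the Fourier module recovers the spec values exactly at
zero noise — an analytic oracle for the whole front half of the pipeline.
Inter-annual variability is a per-year additive scalar (absorbed into A0 by
the year-averaging, like any mean shift in real data); observation noise is
i.i.d. Gaussian per observation (default sd 0.02, a typical residual level
for quality-screened 16-day NDVI composites); values are clipped to [−1, 1].
Layouts are rectangular blocks or seeded Voronoi patches; two independent
seeds separate the landscape from the fire process so fire statistics can be
replicated over a fixed scene. Ignition pixels are drawn with probability
proportional to the class fire multiplier, making the true selection ratio
σ_c = m_c / Σ_k (a_k/A)·m_k exact. The default demo scene uses four classes
whose A0 rises while A1, A2 and the fire multiplier fall from class 1 to 4,
the empirical gradient of real phenological fuel classes.

What the generator does not emulate: spatial autocorrelation of noise,
mixed pixels at patch borders, cloud/quality-flag artefacts, topographic
effects, within-season fire timing. Passing tests therefore demonstrate
correctness of the algorithms under a clean signal model, not robustness to
every artefact of real imagery.

## Numerical and testing choices

Synthetic test problems are kept small (40–100 pixel grids, hundreds to
thousands of simulated fires, 199–999 randomization replicates for
calibration sweeps; 10⁴ replicates where a null-mean convergence check needs
them), sizes at which every stage's oracle is exact or its sampling error is
controlled explicitly. Randomized procedures take explicit integer seeds and
are bit-reproducible; the pipeline report records every seed, replicate
count and parameter and contains no timestamps, so a rerun is byte-identical.
Raster I/O writes GeoTIFFs through tifffile with the geotransform in
standard GeoTIFF tags; only north-up transforms are supported and CRS
mismatches raise rather than reproject.

## Known limitations

- Absolute Fourier amplitudes (hence the numeric meaning of the scale
  parameter) are implementation-relative; compare scales only within one
  normalisation convention.
- Mutual-best-fitting merge order is one deterministic member of the FNEA
  family; segment boundaries on noisy data can differ from other
  implementations even at identical parameters.
- Per-unit σ treats units as exchangeable sampling units; spatial
  autocorrelation between neighbouring units is not modelled, so
  permutation p-values on strongly autocorrelated landscapes are
  anti-conservative.
- Cell-level significance of published aggregated contingency tables can
  only be approximated from the tables themselves (the per-fire label
  vectors are not recoverable); the package reproduces the direction
  pattern and the table-wide χ² exactly, not per-cell p-values.
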