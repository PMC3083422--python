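# Methods

## Multi-event microdosimetry

### Model and assumptions

A sensitive site is a unit-density (1 g/cm³, tissue-equivalent) sphere of
diameter *d*; its Cauchy mean chord length is 4V/S = 2d/3. Energy
deposition events — traversals of secondary charged particles set in
motion by the neutron field — are assumed statistically independent, so
the event count at absorbed dose *D* is Poisson with mean
n = D/z̄_F, where z̄_F is the frequency-mean specific energy per event.
For a lineal-energy description, z̄_F = y_F·l̄·(1.602×10⁻¹⁶ J/keV)/m with
m the site mass, which reduces to z̄_F ≈ 0.2040·y_F/(ρd²) Gy for y_F in
keV/µm and d in µm. Consequences used throughout: n is linear in dose and
proportional to d² at fixed y_F, and the probability of k or more events is
the Poisson tail F_k = P(N ≥ k), with the closed form
F₂ = 1 − (1+n)e^(−n).

Assumptions worth stating explicitly:

* **Pure Poisson event counts.** One event = one statistically independent
  traversal. A calculation propagating a full measured single-event
  spectrum through secondary-particle transport can differ from the pure
  Poisson tail by of order 10%; the package's contrasts are therefore
  checked to 15% relative tolerance, not to printed precision.
* **Calibration by reference point.** Measured 14 MeV y_F values are
  instrument- and field-specific, so the default calibration anchors the
  model at a single known (D_ref, d_ref, F₂_ref) condition —
  (0.2 Gy, 1 µm, 0.3%) in the bundled configuration — by inverting the
  closed form (bisection/Brent, |Δn| < 1e-12) and scaling
  n = n_ref·(D/D_ref)·(d/d_ref)². A y_F-based path is provided for users
  with measured spectra; the two paths agree exactly when the reference
  point is itself generated from a y_F (tested).
* **Gamma contamination ignored.** A few percent of gamma dose in a D+T
  neutron field changes n by the same few percent, well inside the model
  tolerance above.

### Compound-Poisson distribution numerics

The multi-event specific-energy density is
f(z) = Σ_{k≥0} e^(−n)n^k/k!·f₁^(*k)(z) with the k = 0 term kept as an
explicit point mass at z = 0. Implementation choices:

* uniform grid of 2¹² points spanning [0, n·m₁ + 12·√(n·m₂)] (m₁, m₂ the
  first two moments of f₁), extended to cover at least 4 single-event
  supports at small n; f₁ is linearly interpolated onto the grid and
  renormalized there;
* the Poisson sum is truncated at the smallest K with tail mass < 1e-9;
* k-fold convolutions are built by iterated `np.convolve` with Δz scaling.

Invariants asserted in tests: total mass 1 ± 1e-6; mean = n·m₁ (hence = D
when n = D/z̄_F) to 0.1% relative; sup-distance of the CDF from a seeded
100,000-draw Monte-Carlo sampler (an independent inverse-CDF + Poisson-sum
implementation) below 0.01.

## Synthetic data generator

The generator produces the statistical structure the pipeline assumes,
with planted truth for recovery testing. Defaults encode the study
conditions: 28,000 one-spot-per-gene probes; conditions 0.2 Gy/6 h,
0.2 Gy/24 h, 1 Gy/6 h, 1 Gy/24 h; two replicate hybridizations per
condition; four mice per group plus a sham calibrator group.

* **Arrays.** Mean log₂ intensity A ~ Normal(10, 1.5) per spot (log-normal
  intensities, fixed choice documented here); measured
  M = planted log₂fc + bias(A) + Normal(0, spot_sd) with spot_sd = 0.1 by
  default; the dye bias is the cubic
  0.3 − 0.1u + 0.02u² + 0.01u³ (u = A−10), a few tenths of a log₂ unit as
  on uncorrected two-channel slides. Channels are reconstructed from
  (A, M), clipped at 65,535 scanner units; 2% of spots are flagged bad and
  1% collapsed into the background (~100 ± 10 units).
* **Planted blocks.** A 40-gene keratin-like block (+1.2 log₂ at
  0.2 Gy/6 h, −0.4 at both 1 Gy conditions) and a 10-gene S100-like block
  (+1.0 at both 0.2 Gy conditions); every other gene is null. Only the
  S100-like block satisfies "≥ 2-fold in ≥ 2 conditions", which makes it
  the target set of the recovery tests.
* **qPCR.** Reference gene at Ct ≈ 20; target Ct = reference + fixed gene
  offset − planted log₂fc (efficiency exactly 2); two technical duplicates
  with Normal(0, ct_sd) error, ct_sd = 0.15 cycles by default (typical
  technical-duplicate scatter).
* **Densitometry.** Normal(group median, spread) over 4 areas × 4 mice per
  group with 3×-shifted outliers at a configurable rate, plus a background
  channel.

What the generator deliberately does **not** emulate: print-tip/spatial
artifacts (normalization is global, as in the pipeline), dye-swap designs,
probe-sequence effects, correlated biological variation between pooled
mice, and array-to-array scale differences. Passing recovery tests
therefore demonstrates correctness of the pipeline's statistics under its
own assumptions, not performance on any real hybridization.

## Selection rule

A gene is modulated iff |mean log₂ ratio| ≥ log₂(1.5) in ≥ 2 of the 4
conditions (up- and down-modulation both count) and the replicate ratios
differ from zero by a two-sided Student t-test at p < 0.05 in every
passing condition, with no multiple-testing correction.

**Variance estimate of the t-test.** With two replicate hybridizations a
per-condition t-test has a single degree of freedom (critical t = 12.7);
its power at a planted log₂fc of 1.0 with replicate SD 0.1 is only ≈ 0.73
per condition, so requiring two conditions would reject almost half of the
genuinely consistent genes on replicate-agreement luck alone. The default
(`t_mode="pooled"`) therefore judges each condition's mean against the
gene's replicate variance pooled across all conditions
(df = conditions × (replicates − 1) = 4), which is the natural estimate of
a gene's technical scatter when replicate noise does not depend on
condition — an assumption that holds in the generator and approximately on
real slides. The strict per-condition form remains available as
`t_mode="per_condition"`.

**Spot QC interacts with recovery.** Genes missing in any replicate after
spot filtering (flagged, saturated or dim spots) are dropped before
selection and counted in the log; with the default artifact rates roughly
a third of genes are lost this way across 8 arrays. Recovery is therefore
reported as the sensitivity of the selection rule among planted genes that
reach it, alongside the absolute counts.

## Clustering

UPGMA (unweighted average linkage) on Euclidean distances between
condition profiles, maintained by the Lance–Williams update. Determinism
is pinned: exact distance ties merge the pair whose clusters contain the
lowest original gene index, and the exported leaf order traverses each
merge left-subtree-first with "left" = the child containing the smaller
minimum leaf index. Correctness is established against two independent
oracles — a brute-force agglomerator that recomputes cluster distances
from raw member pairs at every step, and scipy's average-linkage
implementation compared through cophenetic distance matrices. Heat-matrix
export clips to ±3 log₂ units for display only; clustering always uses
unclipped values.

## Group statistics

* **ΔΔCT**: technical duplicates are averaged before ΔCt (the arithmetic
  mean of Ct values); the calibrator baseline is the mean ΔCt over sham
  mice, so calibrator folds have geometric mean exactly 1.
* **Whisker boxes**: Tukey convention — quartiles by linear interpolation,
  whiskers at the most extreme points within 1.5×IQR, the rest outliers.
* **ANOVA/Tukey**: standard one-way decomposition (scipy); the Tukey HSD
  test is implemented directly on the studentized-range distribution with
  a cached critical value so that 10,000-replicate error-control
  simulations run in seconds; it handles unbalanced groups via the
  Tukey–Kramer standard error and matches scipy's `tukey_hsd` decisions on
  random fixtures. Measured family-wise error on a 4-group null
  (n = 4 per group): 0.047 at nominal 0.05.
* **Median CI (Ki67)**: distribution-free order-statistic interval from
  inverting the sign test at 95%. With fewer than ~6 values the nominal
  level is unattainable; the widest interval is then returned together
  with its achieved coverage (87.5% at n = 4) and a warning. Coverage is
  verified by simulation at n = 16 areas (4 mice × 4 areas).
* **Degenerate inputs** raise dedicated errors: zero within-group
  variance (ANOVA), zero-variance vectors (correlation), empty samples.

## Problem sizes

The test suite and drivers run the microarray pipeline at the full default
scale (28,000 genes × 8 arrays, a few seconds), the Tukey error-control
simulation at 10,000 replicates, the Monte-Carlo convolution check at
100,000 draws, and the clustering oracle on 100 random 6-gene fixtures —
sizes chosen so the whole suite completes in well under a minute while
keeping Monte-Carlo error far below every asserted tolerance.

## Known limitations

* The Poisson multi-event model ignores spectrum shape when computing
  event-count probabilities; only the compound-Poisson distribution uses
  the single-event spectrum. Site-size-dependent changes of the
  single-event spectrum itself (relevant below ~0.5 µm) are not modeled.
* The bundled single-event spectrum is a synthetic gamma-shaped stand-in
  with the qualitative features of a recoil-proton-dominated 14 MeV field,
  not a measured spectrum; quantities that depend only on its mean are
  exact by construction, shape-dependent quantities are illustrative.
* The selection rule inherits the study's choice of no multiple-testing
  correction; at 28,000 genes the fold-change gate, not the t-test, is
  what keeps the false-positive rate low.
* Real GenePix exports carry many more columns and block/row/column
  geometry; the reader consumes the minimal seven-column dialect and
  ignores spatial structure.
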