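# Methods

This note documents the models implemented in `pauniq`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real data.

## Probabilistic species-to-PA assignment

Occurrence data are presence/absence per square grid cell (default side
10 km, planar km coordinates throughout; no geodesic math — at the grain
of the analysis a projected plane is adequate, and all synthetic tests
are planar). A PA polygon covers fraction `c_k ∈ [0,1]` of each occupied
cell `k`; the coverage fraction is taken as the probability that the
species' within-cell location falls inside the PA, i.e. sub-cell
placement is uniform and independent across cells. The cumulative
presence probability is the complement product `p = 1 − ∏(1 − c_k)`.

Numerics: the scalar operation uses the plain complement product, which
is exact for the canonical worked example (1 − 0.8·0.5 = 0.6 in IEEE
doubles); underflow of the product only occurs when `1 − p` is already
below double resolution, where the correct answer is p = 1. The
vectorized matrix builder instead accumulates `Σ log1p(−c_k)` so the
whole PA × species matrix is a single occupancy-by-log-complement
matmul; a coverage of exactly 1 is floored at log-complement −800, which
underflows `expm1` to −1 and yields p = 1 exactly. The two routes agree
to 1e-12, which the test suite asserts against a 2^n enumeration oracle.

PAs without boundary data get a circular buffer of their reported surface
area around the centroid, polygonized as a regular 256-gon (configurable;
relative area error ~1e-4, well inside the 1e-3 contract). Coverage is
`area(cell ∩ PA)/area(cell)` via shapely with an STR-tree over the land
cells. Marine cells and species are dropped at load time; PAs with known
incomplete reporting are removed by an explicit exclusion list, not
auto-detected.

## Richness, rarity and the area-controlled surplus

- `Richness_RS = Σ_i p_ij` (expected species count; 0 for an empty PA).
- Conservation weight `w_i = 1/frequency_i`, the inverse occupied-cell
  count over the **full** land grid. Weights are never recomputed on
  subsets: they estimate region-wide rarity.
- `Richness_Rarity_weighted = Σ p·w`; `Rarity_Mean` is their ratio, set
  to 0 for an empty PA and bounded by 1 (attained only by certain
  presences of single-cell endemics).
- SAR candidates: Arrhenius `S = b·A^c`, Gleason `S = y + z·ln A`
  (natural log; the semi-log model's base is a free convention and ln
  keeps `z` interpretable per e-fold of area), and a zero-intercept
  linear null `S = m·A`. All three minimise untransformed SSE on the
  richness scale, because the surplus index is defined on that scale.
  The power model is fitted with `scipy.optimize.curve_fit` (b > 0
  enforced), initialised from a log–log OLS; Gleason and the null have
  closed-form OLS solutions.
- Model selection by Gaussian AIC, `n·ln(SSE/n) + 2k` with `k` = number
  of regression parameters + 1 for the error variance; only differences
  matter. Ties (ΔAIC < 1e-9) break toward the simpler model. SSE is
  floored at 1e-300 inside the log so exact interpolation stays finite.
  AICc is available behind a flag, off by default.
- `%Surplus = 100·(observed − fitted)/fitted`, recomputed per analysis
  subset (all PAs / NP-only / MAB-only / per taxon) because the SAR is
  refitted on the subset in use.

## Beta diversity

Pairwise dissimilarity between PA probability vectors uses the
Bray–Curtis partition of Baselga (2013): with `A = Σ min`,
`B`, `C` the site-specific remainders, `total = (B+C)/(2A+B+C)`,
`balanced = min(B,C)/(A+min(B,C))`, `gradient = total − balanced`.
Probabilities enter raw — converting them to pseudo-abundances would add
unfounded precision, and the index only requires non-negative numeric
vectors. A pair of all-zero vectors is an error by default (empty PAs
are excluded upstream); the per-PA summary drops all-zero rows and
reports them as missing. The per-PA score is the mean of its pairwise
values against all other PAs; the SD of the pairwise totals (population
SD over the partner set) measures how variable that differentiation is.
The full dense pairwise computation is used — at a few hundred PAs
(~10^5 pairs) no approximation is warranted.

On binary vectors the partition reduces to Sørensen (total) and Simpson
(balanced) dissimilarities, which the tests verify against direct
set-formula computation.

## Null model and per-nation tests

The null model redistributes every species uniformly at random over the
land cells, without replacement, conserving its frequency (hence its
conservation weight) — the weakest null consistent with arbitrary
reporting restricted to the observed species and their totals. No
habitat or spatial constraint is imposed. The engine draws each
simulated occupancy from per-row order statistics of one uniform matrix
and evaluates all PAs in a single matmul, so the prescribed ensembles run
in seconds.

Per nation and metric (transboundary PAs excluded from national
aggregation, retained in region-wide computation):

- **vs null**: paired two-sided Wilcoxon signed-rank of the nation's
  observed per-PA values against each PA's null expectation. The pairing
  summary is the per-PA mean over the ensemble (median behind a flag).
- **vs rest**: unpaired two-sided Wilcoxon rank-sum of the nation's
  observed values against all other single-nation PAs.

Both tests use the exact null distribution for small tie-free samples
(n ≤ 25) and the normal approximation with continuity/tie correction
otherwise; the suite checks exactness against full enumeration. Nations
with fewer than `min_n = 5` usable PAs are reported untested (NaN),
never as p = 1. No multiple-testing correction is applied by default
(raw p < 0.05 flags); a Holm correction can be applied downstream from
the returned p-values. Region-wide null medians/IQRs pool PAs across all
simulations (per-simulation medians behind a flag).

## Leave-nations-out cross-validation

Each run keeps `n_keep` of the nations (default 20 of 25), drops the PAs
and occurrence records of the excluded nations, refits the SAR and
recomputes `%Surplus` and the dissimilarity summaries against the
retained PAs only. Conservation weights stay fixed: only a lack of
reporting is being emulated, so the full-region weights remain the best
rarity estimates. The per-PA SD across the runs in which the PA was
retained is the uncertainty measure; it is missing for PAs retained in
fewer than two runs (so a single run reports no SD at all).

## Spatially corrected correlation

Pearson's r between per-PA metrics, with significance from a modified
t-test that replaces n by an effective sample size: distance classes
over the PA centroid pairs (Sturges' rule on the pair count sets the
class number), Moran's I of each variable per class, implied spatial
correlation matrices `Rx`, `Ry`, `var(r) ≈ tr(RxRy)/n²`, and
`n_eff = 1 + 1/var(r)` capped at n (a Clifford–Richardson/Dutilleul-type
estimator). On spatially independent data the correction is close to a
no-op (effective n within ~15% of n), which the suite checks against the
uncorrected t-test. External per-PA scores (e.g. published
irreplaceability values) are consumed as an input column for correlation
only — they are never recomputed here.

## Synthetic scenarios: what the defaults mean

The generator's defaults are the package's standard study conditions,
chosen once a priori:

- grid 48 × 36 cells of 10 km (1728 cells, 172,800 km² of land);
- 12 contiguous rectangular nations (contiguity matters for the spatial
  correlation tests), 10 PAs per nation;
- PA areas log-uniform on 150–750 km², circular, non-overlapping — a
  plausible interquartile range for European national parks. The spread
  was fixed by a design-time power analysis: per-PA richness scales
  ~linearly with area at these coverage fractions, so the rank-sum test
  of one nation against the rest compares a ~halved copy of a broad
  area-driven distribution with the original. With log-range
  L = ln(750/150) ≈ 1.61 the stochastic-dominance probability under a
  50% deletion is ≈0.84, which at 10 vs 110 PAs gives ≳90% power at
  α = 0.05 — the regime the calibration/power tests are specified in.
  A 30-fold area range would leave the unpaired test underpowered at
  these sample sizes regardless of implementation;
- 350 species with discrete power-law frequencies `P(f) ∝ f^−1.3`
  truncated at 1500 cells, giving a right-skewed rarity spectrum with a
  realistic share of common species and per-PA richness of a few dozen;
- species placement uniform by default (`aggregation_spread = None`),
  i.e. the aggregation-spread → ∞ limit. This makes the unbiased
  scenario an exact draw from the null model, which is what calibrates
  the type-I error of the nation tests. Aggregated placement (truncated
  Gaussian kernel around a random centre cell, Gumbel-top-k weighted
  sampling without replacement) is available and tested, but a
  calibration scenario must satisfy its own null;
- under-reporting: each (species, cell) record in a biased nation is
  deleted independently with the configured probability; the `biased`
  preset deletes 50% of one nation's records.

Presets: `clean` (the conditions above), `biased` (one nation at 50%
deletion), `nested-pas` (overlap allowed, MAB reserves enclosing ~30% of
the national parks).

What passing tests show — and do not. The calibration and power results
demonstrate that the machinery is statistically sound under its own
assumptions (uniform null, independent species, area-driven richness).
Real reporting data add spatial aggregation, inter-species dependence,
taxon-specific effort and genuinely non-random biogeography; there the
null-model flags read as "inconsistent with arbitrary reporting", not as
proof of under-reporting, and absolute dissimilarity levels depend
strongly on the PA selection. The package deliberately does not target
any published real-data value ranges.

## Problem sizes used in the shipped checks

The statistical acceptance checks run the full prescribed scenario
(12 nations × 10 PAs, 350 species) with 200 null simulations per dataset
and 20 replicate datasets per condition, and 100 replicates of n = 100
for SAR recovery — sizes at which the vectorized engine completes the
whole suite in about two minutes on one core. Users reproducing the
original 1,000-simulation design can simply raise `n_sims`/`n_runs`; the
engine scales linearly.

## Known limitations

- Coverage uses raw geometric fractions; no clipping of PA buffers to
  coastlines, and no areal-interpolation model of within-cell occupancy.
- Independence of presence across cells is assumed as stated; no spatial
  covariance correction in the assignment step.
- The effective-sample-size estimator is one member of the modified
  t-test family; distance-class count and binning are configurable but
  equal-width classes are assumed.
- The SAR families are deliberately limited to the two classical models
  plus the linear null; no logistic/Lomolino fits, and no nested SAR
  construction.
- `PlacementError` is raised, not recovered from, when a requested PA
  area cannot fit inside a nation after bounded retries.
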