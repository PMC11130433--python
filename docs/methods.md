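# Methods

This note records the statistical models, the synthetic-data generator, the
numerical choices and the open design decisions behind `tempoqtl`, in the
order the pipeline runs them.

## Trait derivation and quality control

Raw inputs are long-format daily measurement tables per plant: pixel counts
from one top view and two side views, height and hull-area pixels, daily
water added (g), and endpoint fresh weight (g). Derivation proceeds in a
fixed order; permuting input records never changes the result.

**Composite area.** `area = (tv + sv1 + sv2) * scale(DAP)`. Zoom scale
factors are configuration inputs (one factor per DAP interval; default 1.0)
because platforms change optical zoom as plants grow; the derived area is
comparable across zoom changes by construction. Height uses the square root
of the area scale factor (height pixels scale linearly with zoom, area
pixels quadratically).

**Germination and exclusion.** A plant's germination day is the earliest
DAP with a positive top-view area; the accession-level date is the
replicate mean. A plant is called dead when its top view is zero for five
consecutive days after prior germination (no operational death rule exists
upstream, so this is the package's definition). An accession is retained
when at least two plants germinated and survived past the exclusion cutoff
(default 46 DAP).

**Outlier fence.** A value is removed (flagged, never imputed) when it is
more than `k = 40` median absolute deviations from the median; when
MAD = 0 the series is left untouched (the rule is undefined there, and a
40-MAD fence only targets gross image artifacts). The fence is applied
cross-sectionally — within one trait and DAP, across plants. Applied along
a plant's time series instead, the fence spans the whole dynamic range of a
growth curve (seedling to adult), so an early-season artifact inflated 50x
can still sit inside it; cross-sectionally it is always extreme relative to
its cohort. This reading is a package decision; the upstream description
("on each phenotype") does not fix the grouping.

**Smoothing.** Each plant's daily series per trait is smoothed by locally
weighted polynomial regression (tricube weights, local quadratic, span 0.5
of the series), and the fitted values replace the raw ones downstream. The
smoother is written in-house because the available lowess implementations
are local-linear only; designs are centered at each evaluation point for
conditioning. Fewer than five points: the series passes through unchanged
with a warning flag. Smoothing is per plant, before replicate aggregation
(whether the original analysis smoothed per plant or per accession is not
stated; per plant is flagged as the assumption here).

**Aggregation and derived traits.** The accession value is the replicate
median. Biomass is calibrated by OLS of endpoint fresh weight on area at
the calibration day (default 51 DAP, the last day before plants overlap the
camera field), applied to all days and floored at zero (negative
predictions are not meaningful). WUE(t) = area(t) / cumulative water
through t, undefined (missing, not infinite) while cumulative water is
zero. RGR uses consecutive-day pairs: the difference of replicate-mean log
areas divided by the one-day interval, assigned to the earlier day;
non-positive areas are skipped from the log-mean with a flag.

## Heritability

Per trait and DAP, the one-way random-effects model `Y_ij = mu + g_i +
e_ij` over replicate-complete accessions (default r = 3). The reported
estimator is the balanced ANOVA method of moments, `sigma_g^2 = (MSB -
MSW)/r` clipped at zero, `H^2 = sigma_g^2/(sigma_g^2 + sigma_e^2)`; a
numerical REML fit of the same model is kept as an independent cross-check
and agrees to 1e-6 on balanced data (they coincide at interior optima).
Clipping at zero is the standard resolution for negative moment estimates.

## Population-genetic primitives

Markers are filtered to MAF strictly greater than 0.05 (a marker exactly
at the cutoff is dropped; a 1e-9 tolerance absorbs float rounding) and
zero-variance markers removed; missing dosages are replaced by the marker
mean. Kinship is the Astle–Balding standardized covariance
`K_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1-p_i))` with
allele frequencies taken from the observed post-imputation dosages; it is
invariant to allele relabelling and has diagonal near 1 + f (≈ 2 for fully
inbred lines). Population-structure covariates are the first three
principal components of the column-centered dosage matrix (sign fixed by
making each component's largest-magnitude loading positive). Box-Cox
lambda is chosen by profile likelihood on the grid [-2, 2] in steps of
0.01 (vectorized closed form; `scipy.stats.boxcox_llf` is the test
oracle); `lambda = 0` uses the natural log exactly.

## The multi-locus mixed model

Model: `y = X beta + u + e`, `u ~ N(0, sigma_g^2 K)`, `e ~ N(0,
sigma_e^2 I)`. One eigendecomposition `K = U D U'` rotates the model so
the covariance is diagonal; REML over `delta = sigma_e^2/sigma_g^2` is a
1-D maximization on `log delta in [log 1e-5, log 1e5]` (64-point coarse
grid, then bounded Brent refinement in the bracketing interval — the grid
guards against local optima, Brent gives precision). Pseudo-heritability
is `1/(1 + delta)`.

**Scan.** With variance components fixed at the current null (the
approximate scan used by multi-locus mixed-model software; an exact
per-marker REML refit exists behind `exact=True` for oracle tests), every
candidate marker is tested by a 1-df GLS F-test, vectorized through a QR
of the whitened covariates. Markers collinear with the covariates are
flagged and reported at p = 1. The scan matches an explicit
`Sigma^{-1}`-inversion oracle to 1e-8.

**Forward path and stopping.** Each step re-estimates variance components
under the current cofactors, scans the remaining markers, and adds the
argmin-p marker (ties broken by chromosome and position; candidate order
is fixed by sorting markers genomically). The stop condition —
pseudo-heritability ≤ 0.01 (an optimizer cannot reach exactly zero),
`max_steps` (default 20), or no testable marker — is evaluated after at
least one addition, so the candidate path always contains one model and
model selection, not the stop rule, decides whether anything is reported.
Within each step the p-value of every cofactor is re-computed inside that
step's model (drop-one GLS t-tests), which is what the selection criteria
consume. Backward steps are not taken: the procedure is described as pure
forward addition.

**Model selection.** Multiple-Bonferroni: the largest path model in which
every cofactor has `p <= alpha/m` with `m` = number of markers tested
after MAF filtering (a plain Bonferroni correction; no effective-test
adjustment) — the stringent tier. Extended BIC: the path model minimizing
`-2 logL_ML + k ln n + 2 gamma ln C(m, k)` with `gamma = 1` (the standard
extended-BIC default), ML likelihood maximized separately over delta per
path model. The high-confidence set is the union; markers only in the
extended-BIC model carry the lower-confidence tier.

**Per-day GWAS.** Marker filtering, kinship, PCs and the kinship
eigendecomposition are computed once per trait; each DAP drops
missing-phenotype accessions case-wise (re-decomposing only when the case
set shrinks). Phenotypes are Box-Cox transformed at a given day only when
a normality test rejects at 0.01 (shifted first if zeros are present), and
the fitted lambda is recorded. A failed single-day fit (for example a
constant pre-germination phenotype) is logged and skipped, never fatal.

## Transient tracks, pleiotropy, allele trajectories

The per-day high-confidence sets form a marker x trait x DAP tensor.
Significant DAPs per marker/trait are grouped into maximal
consecutive-DAP runs (strict consecutiveness by default; a gap-tolerance
parameter exists because daily fits are noisy). A track is transient when
more than one run exists or the last run ends before the final day. Both
tiers extend runs; each day keeps its tier tag. Pleiotropic markers are
those significant for two or more traits. Allele-effect series report
per-day means, counts and the alt-minus-ref difference per homozygote
class with a Welch two-sample test (the trait scale is whatever entered
the GWAS); classes below three accessions suppress the test but not the
series.

## Candidate-gene scan

A gene is a candidate for a marker when its body intersects the closed
interval `[pos - w, pos + w]` (default w = 15 kb) on the same chromosome —
closed-interval semantics, so a gene touching the boundary at exactly
15,000 bp is included. Distance is zero when the marker lies inside the
gene, otherwise the gap to the nearest edge; strand is reported but
ignored for inclusion (the window is physically symmetric). Gene-level
GFF3 features only, 1-based inclusive coordinates. The implementation uses
per-chromosome interval trees; tests compare it against brute-force
all-pairs overlap.

## The synthetic-data generator

The generator emulates the data-generating process the analysis assumes,
and records its planted truth for recovery tests.

**Genotypes.** Inbred accessions in `n_subpops` subpopulations under the
Balding–Nichols model: ancestral frequencies Uniform(0.1, 0.9),
subpopulation frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) at the configured
F_ST, one allele draw per accession (dosages {0, 2}; heterozygotes are not
simulated — the target material is inbred). Markers are placed at sorted
random positions on `n_chromosomes`; low-MAF markers arise naturally so
the filter is exercised. Markers are independent within subpopulations: no
local linkage-disequilibrium structure is simulated (planting LD
"shoulders" around QTL is left off by default; the analysis never relies
on LD).

**Growth.** Each plant carries a logistic state `z` with `A(t) = Amax *
sigmoid(z(t))`; `z` advances daily by `r_t = r_base * phase_mult(T_t) *
rate_factor_accession + active rate-QTL effects` — the exact discrete
solution of logistic growth under piecewise-constant rates. The default
temperature schedule is three phases (15 °C for 31 days, 24 °C for 7,
32 °C for the rest) with rate multipliers 0.35 / 0.7 / 1.0 (no published
growth-rate/temperature law for this system; cold strongly suppresses
elongation). QTL modes: `growth_rate` (adds to `r_t` only inside the DAP
window), `asymptote` (shifts Amax), `additive_on_trait` (adds directly to
the trait inside the window). Effects are `effect_size x dosage/2`.

**Accession diversity.** Accessions differ in asymptote (lognormal,
CV 0.25), intrinsic rate (lognormal, CV 0.08) and mean germination day
(normal, SD 2 d around day 7; plants jitter ±1 day). These defaults make
the panel's between-accession variation realistic — diversity panels vary
enormously in growth habit and cold germination — and they matter: with a
near-uniform panel, the ~6-day backward spillover of the loess smoother
from a planted QTL window is itself statistically detectable, which says
something about smoothing under implausibly clean data, not about the
method. Experiments that need to isolate a single component (the MAD
filter, the heritability variance-ratio check) switch this diversity off
explicitly.

**Polygenic background and noise.** A single accession effect `b` is drawn
with covariance proportional to the realized kinship and enters
multiplicatively, `A * (1 + gamma b)`, so its contribution scales with
plant size (heritability then changes over the run, as observed in real
panels). `gamma` is sized so that the between:within variance ratio of the
composite area equals the configured `polygenic_h2` under the default
noise model. Measurement noise is relative per camera view
(`measurement_noise_sd`, default CV 0.05; the composite of 20/40/40 view
fractions has effective CV 0.6x that) — purely additive noise would break
the germination rule at seedling sizes. An optional absolute noise term
and a late-run inflation factor (after `overlap_day`, default 42, when
leaves overlap) reproduce the characteristic rise-then-fall of
heritability over time. Height and hull area are monotone transforms of
area (square root and power 1.05) with independent noise.

**Watering, endpoint, defects.** Daily water = the deficit to the fixed
target mass (carrier 342 g + saturation water 250 g + filled pot 600 g =
1192 g), modeled as base evaporation plus size-proportional transpiration;
the target deliberately ignores accumulated biomass, as in the emulated
protocol. Endpoint fresh weight is proportional to final area (5% CV).
A configured fraction of plants never germinate (all-zero top view); a
configured fraction of positive measurement cells is multiplied by 50 and
recorded in the truth object, as are subpopulation assignments,
germination days and polygenic values.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: image segmentation errors other than
multiplicative spikes, LD structure, genotype-by-environment interaction
beyond the shared temperature schedule, spatial/greenhouse-position
effects, replicate-specific batch effects, and death after germination.

**Randomness.** One root seed; every component draws from a child
generator keyed by a fixed label (SHA-256 of the label mixed into the seed
sequence), so adding a component never perturbs another's draws, and all
outputs are pure functions of (config, seed).

## Validation experiments and problem sizes

`tempoqtl.validation` packages the recovery experiments used by both the
test suite and `scripts/acceptance.py`; sizes were fixed once, before the
experiments were first run, to complete in minutes on one CPU:

- scan oracle: one n=50, m=200 instance, spectral vs explicit-inverse GLS
  p-values (agreement to 1e-8);
- familywise error: 200 null runs (n=100, m=500, kinship from the
  simulated genotypes), share of runs with a non-empty mBonf model
  (expected ≈ alpha, band 1–9%);
- power: 100 runs (n=200, m=500), planted additive QTL explaining 22.5% of
  variance, share of runs where it is the first cofactor (≥ 90%);
- transient recovery: 20 end-to-end runs (n=200 accessions x 3 replicates,
  m=500, 45 days, rate QTL active DAP 20–30, effect 0.08/day), success =
  significant DAPs intersect [20, 35] with none before DAP 15 (≥ 90% —
  a rate effect leaves a persistent level difference, so significance may
  outlast the window but must not precede it);
- heritability: 100 replications of 300 accessions x 3 replicates at true
  H² = 0.5 (mean within ±0.05);
- Box-Cox: 50 replications each of lognormal (lambda 0 ± 0.1) and normal
  (lambda 1 ± 0.25) samples at n=500;
- RGR: exact exponential growth, all 990 interval choices over 45 days
  (machine precision);
- clustering: 3 planted logistic archetypes x 30 accessions at 2% noise
  (adjusted Rand index ≥ 0.9);
- ideotypes: 300 accessions vs an independent count-based brute-force
  filter (exact set equality);
- candidate windows: 1,000 random marker/gene configurations with pinned
  15,000 bp boundary cases vs all-pairs overlap (exact agreement);
- MAD filter: 10,080 top-view cells, 1% injected 50x outliers on a
  homogeneous cohort (recall ≥ 99%, false removal ≤ 0.1%).

## Known limitations

- The approximate scan holds variance components fixed within a step;
  p-values for markers with very large effects are slightly conservative
  relative to a full per-marker REML refit (the exact path exists but is
  O(m) slower).
- extended-BIC model likelihoods are ML (not REML), the standard choice,
  so its selections are not invariant to adding covariates.
- The loess smoother propagates information ~half a span backward in
  time; onset days of transient tracks are therefore conservative by one
  to three days, and detection can precede a true effect window by a few
  days when between-accession variation is very small.
- Heritability assumes balanced replication; accessions missing replicates
  are dropped rather than modeled.
- The pipeline's cache keys on configuration and input checksums only; it
  does not detect hand-edited outputs.
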