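# Methods

This note documents the models, assumptions and numerical choices
behind `vivovitro`, in the order data flows through the pipeline.

## Study design encoded in the defaults

The pipeline is shaped around a paired single-donor design: a
volunteer and a SHIME bioreactor inoculated with the volunteer's
faeces receive the same 28-day dietary intervention, with an LGG
probiotic supplement on days 1–14 and a washout on days 15–28.
Defaults in `reference.py` encode that design: sampling on days
3, 6, 8, 10, 12, 16, 18, 22, 25 and 28 plus baselines (day 0 in both
environments and a pre-stabilisation inoculum in vivo, placed at day
−7 as a configuration choice — the true calendar offset of the
inoculum is not part of the data), giving 12 in vivo and 11 in vitro
samples; six configurable ordination outliers; prevalence cutoffs of
9-of-12 and 8-of-11 (the general default is ⌊0.75 n⌋, which reproduces
both).  Sample-to-day mapping lives in the metadata table; sample
names are treated as opaque identifiers.

## Feed formulation

Daily macronutrient intakes are converted to feed-medium
concentrations in four steps: residue fractions (fibre 0.83,
sugars/carbohydrate 0.011, protein 0.16 — ileostomy-study estimates of
what escapes small-intestinal absorption), per-day normalisation,
nutrient→ingredient factors (animal protein→special peptone 1:1,
non-animal protein→yeast extract 1:1.54, resistant starch→starch,
pectin→pectin, pooled arabinogalactan+arabinoxylan→xylan+gum arabic),
and a glucose correction subtracting 2.9% of the yeast-extract mass
from the sugars target (clamped at zero with a warning — small sugar
targets are legitimate).

Two points were genuinely open and are resolved as package choices:

* **Normalisation rule.** We scale every day's residues by
  `k = soluble_fiber_target / soluble-fibre residue` with the target
  defaulting to the standard feed's 7.7 g/L.  A published experimental
  feed whose soluble fibre varies day to day implies the original
  procedure differed in detail; ours is exact, documented and
  configurable.  A consequence worth knowing: the summary of a
  formulated series is the mean of daily recipes, which is *not* the
  recipe of mean intakes; the discrepancy is largest for glucose,
  a small difference of two normalised terms.
* **Xylan : gum arabic split.** No split rule is stated for the pooled
  fibre ingredient; we use the standard feed's 0.5 : 1.2 proportion.

Fat and insoluble fibre are not formulated (the feed model adjusts
nutrient proportions only).  Mucin (2 g/L) and L-cysteine (0.5 g/L)
are fixed constituents.  Reporting precision is one decimal g/L;
computation is full precision.

## Community metrics

Chao1 uses the bias-corrected estimator
`S_obs + F1(F1−1)/(2(F2+1))`, defined when no doubletons exist and
equal to observed richness without singletons.  Shannon is natural-log
entropy; Simpson defaults to Gini–Simpson `1 − Σp²` with an
inverse-Simpson switch.  No rarefaction is applied by default; a
seeded hypergeometric subsampling switch exists.  Presence for
prevalence purposes is raw count ≥ 1.  The F/B ratio is computed per
sample from the phylum labels `Firmicutes` / `Bacteroidetes` and is
reported as NaN (flagged, never infinity) when a sample has no
Bacteroidetes counts.  All implementations of the indices are
delegated to scikit-bio with these conventions pinned.

## Ordination

CLR uses a pseudocount of 0.5 on counts (configurable); rows of the
transformed matrix sum to zero by construction, and the transform is
scale-invariant up to the pseudocount.  When only a subset of taxa is
analysed (the shared prevalent genera), CLR is computed on the **full**
composition first and then subset.  Computing CLR within the
subcomposition instead would let one strongly responding genus
contaminate every other selected genus through the subcomposition's
geometric mean; the full-composition variant preserves each genus's
log-ratio to the whole community.

PCoA uses presence/absence Jaccard distances, double-centring and an
eigendecomposition (scikit-bio); negative eigenvalues are reported,
not corrected.  PCA is centred but not unit-scaled on CLR data (CLR
already places taxa on a common log scale); diet matrices arrive
z-scored.  Sign convention: within each component the largest-|loading|
entry is made positive, making scores reproducible across linear-
algebra backends.  An optional outlier flagger marks samples whose
median PCoA distance to same-environment samples exceeds the
environment median by 3 MADs (with a small numerical floor on the
MAD); it is off by default since the study's outlier list is explicit
configuration.

## Lag-window scan

The trailing window of length `w` for a sample taken on day `t` covers
days `t−w … t−1` (the 24-hour analysis is `w = 1`).  Samples whose
window extends before the available diet history are dropped for that
`w` rather than averaged over a shortened window, keeping windows
comparable at the cost of varying `n` across `w`.  Correlations are
Spearman on CLR abundances by default (a relative-abundance switch
exists and is recorded in outputs; rank correlations are *not*
invariant to the choice).  Undefined correlations (constant series)
count as non-responders.  The optimal window maximises the responder
count, ties resolved to the smallest window.  Default sweep range is
1–14 days; the default responder threshold is ρ > 0.7.  The
"protein-to-soluble-ratio" exposure is defined as total protein
divided by soluble fibre per day.  Taxa responding to several
exposures are counted once.

## Divergence model

Within each environment, windowed exposures are z-scored (ddof = 1),
which cancels the g/day vs g/L units.  Pooled PCAs reduce the CLR
microbiota matrix (shared prevalent genera at genus level, or all
phyla) and the standardised diet matrix (four macronutrients by
default: soluble fibre, sugars, non-animal protein, animal protein) to
two components each.  The model

    PC_micro ~ (PC1_diet + PC2_diet + Probiotic) × Environment

is fitted by OLS with sum-to-zero (±1) coding for both factors —
required for Type III tests to be meaningful — and each term is tested
by full-vs-reduced model comparison: `SS_T = SSE(without T) −
SSE(full)`.  Variance explained is reported both as `SS_T / total
corrected SS` (the headline share) and as partial eta squared.
Because which diet PC carries an environment-specific diet response is
a rotational accident of the diet PCA, the package also provides a
joint 2-df test dropping both `PC_diet:Environment` columns at once;
this is the recommended answer to "does the diet response differ by
environment?".  No repeated-measures correlation structure is
modelled: samples from the same subject/reactor over time are treated
as independent, replicating the original analysis design and
inheriting its limitation.

## Association report

Spearman ρ is the Pearson correlation of midranks; p-values are exact
(full permutation null of one margin) for n ≤ 9 and t-approximate
beyond.  The Wilcoxon signed-rank test drops zero differences, uses
the exact signed-rank distribution (computed by convolution over
doubled midranks, so ties are handled) for n ≤ 25, and a continuity-
corrected normal approximation with tie correction beyond.  Both
thresholds are configurable.  Multiple-testing adjustment (BH step-up
or Bonferroni, via statsmodels) is applied separately within each
descriptor family — alpha diversity, F/B ratio, shared genera — and
separately per environment; the two environments are never pooled.
The paired environment comparison of diversity pairs samples by
sampling-day rank (the pairing scheme is configuration).

## Synthetic data generator

The generator is a log-linear latent model with multinomial counting
noise, matching the CLR-based analyses downstream.  For taxon *i* in
environment *e* on day *t*:

    latent = baseline_i + offset_i(e)
           + Σ_k slope_k(e) · z(TM_{lag_k}(exposure_k)(t))
           + boost · [probiotic taxon, e = in vitro, t in days 1–14]
           + N(0, noise_sd)

with counts multinomial over `softmax(latent)` at a Poisson-drawn
depth (mean 20 000).  `TM_w` is the trailing mean ending the day
before sampling — the same definition the scan uses — and z-scores are
taken over the environment's sampling days.

Key default choices, each made once and documented here because the
study reports no effect sizes usable as simulation truth:

* **Roster** (27 taxa): the eight shared core genera actually reported
  as common to both environments, a probiotic genus (Lactobacillus,
  resident in vitro, baseline set so its relative abundance is ~0.5%
  before supplementation and several-fold higher during it), and
  environment-resident genera drawn from the taxa reported as specific
  to faeces or to the simulator.  Residents carry a large negative
  offset (−12 log units) in the foreign environment, making them
  effectively absent there.
* **Environment offsets**: N(0, 1) per (core taxon, environment), plus
  a fixed ±1 "F/B tilt" (Firmicutes up in vivo, Bacteroidetes up in
  vitro) mirroring the observed drop of the F/B ratio after transfer
  to the simulator.  The offset scale is set so that the environment
  separation dominates the first microbiota PC (typical Type III share
  ~60%) while diet-driven variance remains visible on the same axis —
  the variance-share pattern the analysis is designed to resolve.
* **Responders**: eight per environment (ten in vitro), lag 9 days in
  vivo and 12 in vitro, slopes graded 0.6–2.0 on the log scale with
  exposure pairings echoing the study's correlation findings (e.g.
  Akkermansia tracks non-animal protein in vivo and associates
  negatively with it in vitro).  The grading is deliberate: strong
  responders exceed the ρ threshold over a broad band of windows while
  weak ones cross it only near the planted lag, so the responder-count
  curve peaks at the true window.  The in vitro set is slightly
  larger, mirroring the larger prevalent-genus set observed in the
  simulator and compensating for the intrinsically flatter window
  discrimination at longer lags.
* **Diet series**: truncated-normal daily draws around the published
  mean ± SD tables (volunteer g/day; simulator feed g/L), multiplied
  by a shared log-normal daily intake-scale factor (σ = 0.25) that
  makes the macronutrient series positively correlated, as real
  dietary records are — without it the diet PCA has no stable leading
  direction.  The series is stationary: pre-intervention days draw
  from the same experimental-diet process and serve as lag history.
  An optional switch draws pre-intervention days from the standard-
  diet means instead; it is off by default because the resulting step
  change makes trailing means of all window lengths share a monotone
  ramp and blurs lag identification.
* **Noise**: residual log-scale SD 0.3.

What the generator does **not** emulate: sequencing reads, chimeras,
taxonomy mis-assignment, temporal autocorrelation of the community
beyond the planted diet responses, compositional interactions between
taxa, and day-to-day depth trends.  Passing recovery tests therefore
demonstrates that the pipeline's statistics do what they claim on data
matching their assumptions — not that the original biological effects
are re-estimated.

A null configuration (`SimulationConfig.null`) zeroes every planted
effect; under it the divergence model's Environment term and the joint
diet-interaction test reject at close to the nominal 5% (checked over
200 seeds against the binomial confidence band).

## Problem sizes and tolerances

Simulation studies use 200 seeds for null calibration and 100 seeds
for each recovery study at the study's own sample sizes (23 samples,
27 taxa, depth 20 000) — a few minutes on one CPU.  Numerical
tolerances: CLR row sums and PCA orthogonality at 1e−9; PCoA distance
reconstruction at 1e−8; Type III vs sequential SS agreement on
orthogonal designs at 1e−8.  Lag recovery is assessed within ±2 days
of the planted lag; the smallest-window tie rule biases the optimum
slightly downward on count plateaus, which the ±2 band absorbs.

## Known limitations

* The linear model treats longitudinal samples as exchangeable;
  standard errors are optimistic if the community autocorrelates.
* The feed-formulation normalisation is one member of a family of
  rules consistent with its verbal description; inverse validation
  holds exactly for ours.
* Exact Spearman p-values are conditional on the observed tie pattern.
* With ~11 samples per environment, a ρ > 0.7 responder threshold
  leaves both detection and false-positive rates noticeably seed-
  dependent; the window sweep's optimum should be read with its full
  count curve, which the pipeline exports.
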