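# Methods

## Data model

One row per measured fly: sex (F/M), source (laboratory colony vs.
field trap), morph label (winter/summer, known only for lab-reared
flies; field flies always enter as `unknown` and are labelled only by
the classifier), wing length, wing width and hind tibia length in mm
(strictly positive; wing width optional), and for field flies an
ISO-8601 collection date and site. All statistics are computed per sex
throughout, because females are systematically larger than males.

Descriptive summaries report mean ± SEM with the sample (n−1) SD.
Two-group comparisons use the pooled-variance Student's t
(df = n₁ + n₂ − 2), not Welch's, matching how the source cohorts were
compared.

## Allometric size correction

The adjusted ratio is (Y − α)/X with Y wing length, X hind tibia
length and α the intercept of the per-sex OLS regression of Y on X over
laboratory **summer** morphs only. Subtracting α makes the ratio
invariant to where along the allometric line a fly sits, which is the
point of the transform: field flies differ in body size from lab flies
(diet, temperature), and a raw ratio would confound size with morph.
Defaults anchor to intercepts α = 1.003 (F) and 0.762 (M); a
config-level override exists because a slightly different female value
(1.008) also circulates, and the choice is surfaced rather than silently
resolved. Field data are always transformed with the lab-fitted α —
the regression is never refitted on field flies. The slope, residuals
and R² are retained for diagnostics only; the transform consumes α
alone.

## Classifier

A depth-1 CART tree (decision stump) per sex. Candidate cutoffs are
midpoints between consecutive distinct sorted predictor values; the
chosen cutoff maximizes the weighted decrease of Gini impurity
1 − p_w² − p_s². Ties break toward the smaller cutoff, and predictor
selection ties break by the fixed order wing length, wing width, hind
tibia, transformed ratio — both purely for reproducibility. The
decision direction is fixed by the biology (winter ≥ cutoff); if a
training sample's winter mean falls below its summer mean the fit
raises instead of silently inverting. The boundary belongs to winter
(inclusive ≥). Deeper trees, surrogate splits and pruning are
deliberately out of scope: the published criterion is a single
threshold.

## Repeated-split evaluation

"Validation" is Monte-Carlo cross-validation: 500 iterations of a
simple random 70/30 partition without replacement (train size
round(0.7·n), redrawn up to 100 times if a draw leaves a single-class
training set). Per iteration the stump is refitted on the training set;
for the transformed ratio the summer-morph regression intercept is also
refitted on the **training** summer flies only, so no validation
information leaks through the size correction. The final reported rule
uses the across-iteration mean cutoff; summaries keep mean/min/max of
cutoffs and validation error percentages, and the per-iteration values
are retained. The validation error is averaged per iteration across
iterations (the pooled-count alternative would weight iterations by
validation size; with a fixed 30% split the two differ negligibly).
Iteration RNG streams are spawned from a root seed, so iteration i is
identical regardless of the total iteration count. Two alternative
modes exist behind flags for sensitivity analysis: stratified-by-morph
partitioning, and bootstrap resampling of the training set with
out-of-bag validation.

The default simple-random mode runs through an array-based loop that is
draw-for-draw equivalent to composing the public partition / refit /
stump / error operations (asserted in the test suite); the object-based
path serves the alternative modes.

## Density overlap

Per-morph Gaussian KDEs with Silverman's bandwidth per class;
overlap = 100·∫ min(f̂_w, f̂_s) dx by the trapezoid rule on a
1024-point grid spanning both samples padded by 3 bandwidths. The
bandwidth rule is recorded in the result for audit, since overlap
percentages are bandwidth-sensitive at these sample sizes (n ≈ 40–60
per class).

## Phenology

Field records are classified with the lab-trained per-sex rules and
aggregated by calendar month (weekly trap services are summarized
monthly). Years are pooled by default; pooling pools **counts** and
then computes the frequency — never the mean of yearly frequencies.
Months with zero catch inside the observed span are emitted with
n = 0 and an undefined (not 0%) frequency. For synthetic field seasons
the generator's hidden true morphs (kept in dataset provenance, never
in the records) support a confusion-matrix evaluation of the
lab-to-field application.

## Synthetic data generator

No per-fly data are published, so cohorts are regenerated from the
published summary statistics:

* Per sex × morph: hind tibia ~ Normal(μ_t, σ_t), wing width ~
  Normal(μ_w, σ_w), and wing length = a + b·tibia + ε with
  ε ~ Normal(0, σ_r). Marginal SDs are reconstructed from printed SEMs
  as SEM·√n (n is printed alongside). Defaults (mm): female winter
  n=41, wing 2.97±0.020, width 1.23±0.011, tibia 0.80±0.005; female
  summer n=56, 2.39±0.015, 0.99±0.007, 0.73±0.004; male winter n=42,
  2.69±0.018, 1.08±0.025, 0.75±0.003; male summer n=50, 2.15±0.015,
  0.87±0.006, 0.68±0.004 (mean±SEM).
* The allometric coupling is anchored to the published summer
  intercepts: b = (wing mean − α)/tibia mean per sex (1.900 F,
  2.041 M); winter cohorts share the sex's slope with the intercept
  chosen to match the winter wing mean; σ_r² = marginal wing SD² −
  b²σ_t² (floored at 0), so the implied marginal moments match the
  printed table exactly. The published tables give no wing–tibia
  correlation; this construction is the minimal one consistent with the
  printed intercepts, and it is what makes the ratio transform actually
  size-correcting in synthetic data.
* Non-positive draws are rejected and resampled, never clipped (no
  point mass at a boundary). At the default parameters rejection is
  astronomically rare.
* Field seasons are month-indexed two-component mixtures: per month and
  sex, a catch count and a winter-morph proportion; morphometrics come
  from the lab cohort specs (no separate field variance structure is
  published). The default season (June–October, totals 116 females /
  123 males matching the published field sample sizes, winter
  proportion 0.55 → 0.15 → 0.35 → 0.80 → 1.00) emulates the reported
  qualitative pattern: winter morphs present at first detection in
  June, a mid-summer dip, saturation by October. True morphs are hidden
  in provenance so the classifier cannot see them.

What the generator does **not** emulate: non-Gaussian tails, diet- or
host-driven size shifts between sites, trap-type effects,
between-year differences, measurement error structure. Passing
recovery tests therefore shows the *procedure* is correctly implemented
and statistically sound at the published operating point — not that the
published cutoffs are optimal for other regions or rearing conditions.

## Parameter recovery and its precision

Recovery experiments regenerate cohorts at the default parameters, run
the full 500-iteration procedure, and compare mean cutoffs with the
published ones (female/male wing length 2.69/2.42 mm; transformed ratio
2.17/2.31). A single synthetic study is one random draw of ~97 (F) or
~92 (M) flies, and its 500-iteration mean cutoff inherits dataset-level
spread: small for wing length (SD ≈ 0.03 across replicate studies) but
large for the transformed ratio (SD ≈ 0.45), because a summer cohort's
within-group tibia SD (SEM·√n ≈ 0.03 mm) identifies the regression
intercept only weakly — the per-study fitted α has SD ≈ 0.3 mm, and the
ratio cutoff moves by roughly −1.3 per mm of α. The expectation over
replicate studies is unbiased (measured 2.669/2.415 for wing length and
2.173/2.310 for the ratio, against 2.69/2.42 and 2.17/2.31). Recovery
is therefore measured as a replicate-study average: 60 replicates for
wing length and 600 for the ratio, each replicate the full 500-iteration
procedure, giving Monte-Carlo standard errors of ≈ 0.004 and ≈ 0.017 —
small against the published min–max ranges. These replicate counts (and
every other simulation size in the test suite) were fixed from this
variance analysis.

## Numerical notes

* CSV floats serialize with 10 significant digits; round-trips are
  lossless well past 6 digits. Missing optional fields are empty cells.
* Degenerate inputs fail loudly: zero tibia variance (OLS), zero-variance
  KDE samples, single-class or constant-value splits, empty nodes,
  zero pooled variance with unequal means, partitions that cannot yield
  a two-class training set.
* All randomness flows from numpy `SeedSequence` spawning; every stage
  of a pipeline run derives its stream from the run seed in a fixed
  order, so identical config + seed reproduces every artifact byte for
  byte.

## Known limitations

* The stump is trained on laboratory flies only; systematic lab–field
  size differences are corrected only through the allometric transform,
  and only to the extent the summer-morph allometry holds in the field.
* The transformed-ratio cutoff is sensitive to the fitted intercept at
  realistic cohort sizes (see above); users refitting α on their own
  colonies should expect materially different ratio cutoffs and should
  re-run the repeated-split evaluation rather than reuse published
  thresholds.
* Published field-season frequencies cannot be reproduced exactly —
  the underlying field measurements are not deposited; the phenology
  module is validated against synthetic seasons with known mixtures.
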