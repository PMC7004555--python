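# suzukii-morphs

Quantitative discrimination of *Drosophila suzukii* (spotted-wing
drosophila) winter and summer seasonal morphs from wing and body
measurements, and the seasonal phenology of field trap catches that
follows from it.

## The problem

*D. suzukii* overwinters in temperate regions as a distinct "winter
morph" — larger and darker than the summer morph. Morph scoring by
abdominal pigmentation is unreliable for trap-caught flies (specimens
sit in drowning solution and bleach or bloat), so this package
implements a purely morphometric criterion for entomologists running
trapping surveys: measure wing length and hind tibia length (mm), apply
a calibrated threshold, get a morph call.

## The method

Three pieces, each trained on laboratory-reared flies of known morph,
separately per sex (females are larger than males):

1. **Allometric size correction.** A raw wing/tibia ratio only removes
   body-size dependence if the wing-on-tibia regression passes through
   the origin; it does not. The adjusted ratio subtracts the intercept
   α of the OLS regression of wing length *Y* on hind tibia length *X*
   fitted to known summer morphs:

   *Y*<sub>adj</sub> = (*Y* − α) / *X*

2. **Gini decision stump.** The classifier is the first split of a CART
   classification tree: the cutoff *c* maximizing the Gini impurity
   decrease, candidates at midpoints between consecutive distinct sorted
   values. A fly is called **winter** iff its predictor value ≥ *c*
   (winter morphs are the larger phenotype; the direction is fixed, not
   learned). Candidate predictors: wing length, wing width, hind tibia
   length, and the transformed ratio.

3. **Monte-Carlo cross-validation.** 500 random 70/30 train/validation
   partitions; per iteration the stump (and, for the transformed ratio,
   the intercept α) is refitted on the training set and scored on the
   validation set. The reported cutoff is the across-iteration mean;
   the summary keeps mean/min/max of cutoffs and error percentages.

Class separability is quantified as the overlap coefficient
100·∫ min(f̂₁, f̂₂) dx between per-morph Gaussian kernel density
estimates (Silverman bandwidth). Field catches are classified with the
laboratory-trained rules and aggregated into monthly winter-morph
frequencies (years pooled).

No per-fly measurements are published for this system, so the package
includes a first-class synthetic-data generator that reproduces the
published cohort summary statistics (per-sex, per-morph n, mean, SEM for
all three metrics) with a real wing–tibia allometric coupling anchored
to the published summer regression intercepts (1.003 females, 0.762
males). Every stage is tested end to end against it.

## Worked example

Fit rules on a synthetic laboratory study at the published parameters
(41/56 female and 42/50 male winter/summer flies):

```
$ suzukii-morphs fit --seed 42 --out demo --n-iterations 500
F wing_length: cutoff mean 2.7084 [2.6253, 2.7556], error mean 0.4% [0.0, 6.8966]
M wing_length: cutoff mean 2.3883 [2.3117, 2.475], error mean 2.8786% [0.0, 14.2857]
F transformed_ratio: cutoff mean 1.8743 [1.2244, 2.6601], error mean 3.0759% [0.0, 13.7931]
M transformed_ratio: cutoff mean 1.9015 [0.4003, 3.1361], error mean 5.0357% [0.0, 21.4286]
report: demo/report.json
```

Each line is one sex × predictor: the mean [min, max] classification
cutoff over the 500 train/validation iterations, and the mean [min, max]
validation misclassification rate. For this seed, females with wing
length ≥ 2.71 mm would be called winter morphs with a mean
cross-validated error of 0.4%. Wing-length cutoffs are tight across
iterations; transformed-ratio cutoffs vary more because the summer
intercept is refitted per iteration from a small cohort. Other
subcommands: `simulate` (write synthetic lab/field CSVs), `overlap`
(density overlap), `phenology` (classify a field CSV into monthly
winter-morph frequencies), `run` (everything, including the field
season). Real data enter as CSV with header
`id,sex,source,morph,wing_length_mm,wing_width_mm,hind_tibia_mm,collection_date,site`.

From Python:

```python
import suzukii_morphs as sm

lab = sm.generate_lab_dataset(sm.default_lab_specs(), seed=42)
fits = {s: sm.fit_summer_allometry(lab, s) for s in sm.Sex}
summary = sm.repeated_split_evaluation(
    lab, sm.Sex.FEMALE, sm.Predictor.WING_LENGTH, n_iterations=500, seed=1
)
print(summary.final_rule)   # ThresholdRule(sex=F, predictor=wing_length, cutoff=2.70...)
```

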