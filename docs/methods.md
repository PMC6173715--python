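# Methods

## Scope and data model

`lipidmark` implements a complete serum-lipidomics biomarker workflow for
a two-class case-control design. The exchange object throughout is a
subjects × markers table (a pandas DataFrame) with metadata columns
`subject_id`, `diagnosis` (MS/healthy), `age` (years), `sex` (m/f) and
one non-negative concentration column per marker (ng/ml). All estimators
follow scikit-learn conventions (constructor parameters, `fit`,
`transform`/`predict`, fitted attributes with trailing underscores).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream claim is checked.

Per subject and marker, concentration is drawn as

    c = exp(N(log_mean + class_effect·[patient], log_sd))
        + age_slope·(age − 18) + sex_offset·[male],   clamped at 0.

* Log-normal baselines reproduce the strong positive skew of serum
  lipid concentrations; age and sex enter additively on the raw scale so
  the correction formula's parameters are interpretable in ng/ml.
* Ages are uniform on the configured intervals (patients 18.2–62.8,
  controls 18–53.2 years) — patients are systematically older, so age is
  a genuine confound of the class label. Sex counts are exact
  (round-half-up of the configured fractions: 31/102 male patients,
  118/301 male controls), so the cohort's sex-by-group χ² is a
  deterministic property of the design.
* Default panel: 43 markers across eight lipid classes. Eight are
  informative: GluCerC16, HETE15S, LPA20:4, biopterin, OEA, PEA lowered
  in patients; LacCerC24:1 and C16Sphinganin raised. GluCerC16 carries a
  −2.5 log-SD shift (a marker that discriminates on its own at >90%
  accuracy); the other seven carry ±1.25 log-SD. Eight independent
  1.0-SD rules cannot exceed ~84% balanced accuracy in a rule-sum
  classifier (binomial bound), so the ~95% regime this workflow targets
  requires exactly this kind of one-strong-several-moderate profile.
* The informative markers also carry the published age slopes and
  male−female median offsets (e.g. GluCerC16: −1.6263 ng/ml/yr,
  −10.2439 ng/ml), giving the correction stage real work. Baseline
  log-means were chosen so that the linear age term stays well below
  typical concentrations; otherwise the assay floor (the 0-clamp) would
  censor older subjects and silently erase planted effects. With the
  defaults the clamp rate is ≲0.1% of values; the generator logs the
  count.
* Markers are independent given age, sex and class. Real lipid panels
  are correlated within biosynthetic families; passing tests therefore
  demonstrate recovery of independent planted effects, not robustness to
  correlated ones. An optional shared latent factor was considered and
  left out — it is not needed by any downstream contract and would
  complicate the planted-truth bookkeeping.

## Preprocessing

Order: Grubbs outlier scan → age/sex correction → ln(x+1) → percent
normalization (the last only for distance-based structure mapping and
kNN; classifier fitting uses the unnormalized log scale).

* **Grubbs scan** (one pass per marker, α = 0.05 two-sided, at most one
  removal per marker): G = max|x−x̄|/s against
  G_crit = (n−1)/√n·√(t²/(n−2+t²)), t the α/(2n) Student quantile with
  n−2 df. A flagged value is replaced by the marker's
  leave-one-out median, keeping the table rectangular. On log-normal
  synthetic data the raw-scale scan flags the extreme tail value in a
  fraction of markers (~1 per 2–10 markers at n = 403); this is expected
  behavior of a normality-based screen on skewed data and harmless to
  the pipeline.
* **Confound correction.** Corrected = original +
  (age − reference_age)·Slope_Age − (male ? ΔMedian : 0), with
  reference_age the minimum age of the fitting cohort. For the printed
  formula (which *adds* the age term) to remove a trend, the stored
  Slope_Age must be the negated OLS slope of concentration on age;
  ΔMedian = median(male) − median(female) is used as printed. The
  parameters are fitted **on controls only** by default: patients are
  older and carry the class effect, so a pooled fit absorbs part of the
  disease signal into the slope (measured on synthetic data: fitted
  GluCerC16 trend inflated ~2×, sex differences sign-flipped) and leaves
  residual age association — contradicting the requirement that the
  corrected data show no significant age/sex effects in any marker. A
  `controls_only=False` switch restores pooled fitting.
* Corrected values may be negative and are retained (the formula can
  cross zero; no clamping rule is imposed). In rare cases
  (slope-estimate noise × a 45-year age span on ~1 ng/ml markers) a
  corrected value falls below −1, outside the domain of ln(x+1);
  `zero_invariant_log` raises by contract, while the classifier,
  benchmark and structure paths clip such values to −1 + 10⁻³
  (`safe_log1p`) and log the count.
* `residual_confound_check` reports per-marker Spearman ρ (age) and
  rank-sum p (sex) after correction. Covariate correction removes the
  physiological trend, not the class-mediated age association (patients
  are older *and* shifted); markers whose planted trend is small
  relative to their noise therefore show no individual shrink — the
  contract is per-marker shrink where confounding is visible and
  aggregate shrink over the informative panel.

## Structure mapping

* **Toroidal SOM.** Online Kohonen training on a rows × cols torus
  (default 50×80 = 4,000 neurons, 20 epochs). Weights initialize by
  sampling each variable's observed values; the Gaussian neighborhood
  radius decays linearly from half the smaller grid dimension to 1 and
  the learning rate from 0.5 to 0.01 (these schedules are exposed
  parameters; the defaults are conventional, not canonical).
* **U-matrix.** Height(neuron) = mean Euclidean distance to its 8
  toroidal neighbors' weights — diagonals included, since "immediate
  neighbors" on a rectangular grid naturally includes them. Verified
  exactly against a brute-force oracle.
* **Two-basin partition.** The published workflow reads the watershed
  off a topographic U-matrix display by eye. The automated stand-in
  thresholds heights at a quantile and takes connected low-height
  components on the torus; a descending threshold ladder (default 0.6
  down to 0.05 in steps of 0.05) is scanned and the threshold whose
  *second-largest component holds the most subjects* wins — neuron-count
  ranking is misled by large empty valleys on sparse emergent maps.
  Subjects inherit their BMU's basin; stranded BMUs join the nearest
  basin by toroidal grid distance. On very sparse maps (≈10 neurons per
  subject, e.g. the full 50×80 grid with 403 subjects at moderate effect
  sizes) the inter-class ridge may not close and the partition can fail
  to track the classes; the 20×30 geometry is reliable at this cohort
  size and is what the smoke profile, tests and acceptance script use.
  This is a known limitation of automating a visual step.
* **MCE.** Pairwise Euclidean or correlation distances → minimum
  spanning tree → geodesic = path length along the tree. Centered
  variant: classical MDS (double-centered squared geodesics, top-2
  eigenpairs). Non-centered variant: SVD of the raw geodesic matrix,
  skipping the leading singular vector, which is a near-constant
  centrality component (on collinear data it is even in the position and
  would fold the line in two); components 2–3 carry the structure. Both
  variants orient each coordinate to correlate non-negatively with the
  first input feature for reproducible plots.
* **Agreement score:** balanced accuracy of a binary partition against
  the diagnosis, maximized over the two label permutations.

## Feature selection

Per nested run: a stratified inner split (2/3, mirroring the outer
split) of the training cohort; an equal-group subsample (minority-class
size per class) of the inner training data; a bagged ensemble of
`DecisionTreeClassifier`s (default 500 trees, ≤ 6 candidate features per
split — read as the per-split candidate count, the standard forest
meaning) on bootstrap resamples. Importance is the out-of-bag
permutation measure: per tree, the decrease in OOB accuracy when the
marker's OOB values are permuted, averaged over all trees (trees not
using the marker contribute 0); this is the classical "mean decrease in
accuracy". The ensemble is hand-assembled from sklearn trees because
sklearn's forest exposes no OOB permutation importance; only trees whose
split set includes the marker are re-predicted, which keeps a 500-tree ×
43-marker run at ~1.5 s.

Computed ABC analysis sorts non-negative contributions (negatives are
clipped to 0 with a warning — permutation importances of pure-noise
markers straddle 0), builds the cumulative-fraction curve in the unit
square, and sets the A|B boundary at the curve point with minimum
Euclidean distance to (0, 1) (Pareto point) and the B|C boundary at the
break-even item where the curve's slope first drops to ≤ 1
(contribution ≤ mean). Only set A is consumed downstream. The final
panel size is the modal |set A| over runs (ties toward the smaller
size); members are ranked by set-A membership count, then mean
importance, then name. `expert_veto` removes configured markers and
promotes the next-ranked.

## Symbolic classifier

Per marker and class, a 1-D Gaussian mixture is fitted on ln(x+1)
values by EM (sklearn `GaussianMixture`, diagonal covariance, seeded
k-means init, 2 restarts), with M = 1..3 selected by BIC; M_max = 3 is a
desk-reproducible surrogate for interactive mixture tuning, and BIC on
cohort-scale classes almost always selects M = 1–2. A zero-variance
class is forced to M = 1 with the SD floored at 10⁻⁶.

The decision threshold of a marker is a root of
prior_MS·p(x|MS) − prior_H·p(x|healthy), found by sign-change scanning
(2,001-point grid) plus Brent refinement on the observed data range;
with several crossings the one nearest the midpoint of the class means
is kept. Class priors default to training prevalences (≈0.25/0.75);
with weak markers and imbalanced priors the weighted densities may not
cross inside the data range, in which case the class-mean midpoint is
used with a warning. Equal priors are available by configuration. The
rule direction is ">" iff the patient-class mean exceeds the healthy
mean; thresholds are reported back-transformed (eˣ − 1) to ng/ml on the
corrected scale, and prediction compares raw corrected values against
the ng/ml twin (monotone-equivalent to the log comparison, and the
serialized CSV round-trips bit-exactly because the ng/ml value is the
stored primary).

SF = number of satisfied rules; predict MS iff SF ≥ t. t is chosen from
1..|rules| to maximize sensitivity × specificity on the training
scores, ties toward the smaller t. Raising t is monotone: sensitivity
never increases, specificity never decreases.

## Evaluation

* **Split:** per class, round-half-up of fraction × class size to the
  training side (102/301 at 2/3 → 68+201 train, 34+100 test);
  deterministic given the seed.
* **Metrics:** confusion-matrix measures in percent; NaN for an empty
  denominator. Balanced accuracy ≡ (sensitivity+specificity)/2. ROC
  area is the tie-aware trapezoidal/concordance area (so for a hard 0/1
  predictor AUC equals balanced accuracy exactly); PR area is average
  precision (step-wise interpolation).
* **Bootstrap:** within-class resampling with replacement of the test
  set; the 95% CI endpoints are order statistics of the resample vector
  (index ⌈q·n⌉ of the sorted values); undefined resamples are dropped
  and counted.
* **Sex-balance χ²:** Pearson 2×2 with Yates correction floored at 0
  (max(|O−E|−0.5, 0)); the flooring makes a perfectly proportional table
  score exactly 0 and reproduces the study-design value 2.1738 from the
  counts 31/71 vs 118/183.

## Benchmarks

kNN (k = 5, on percent-normalized log concentrations so Euclidean
distance is scale-free), AdaBoost (500 stumps, sklearn defaults) and
random forests (1,000 trees, √d candidates) are sklearn estimators
behind a thin spec layer; all learners in a comparison share one
stratified split and one evaluation path.

## Problem sizes and runtime

The published repetition counts (1,000 selection runs, 50×80 SOM,
1,000 bootstraps) are the library defaults. The test suite and the
acceptance script use reduced sizes chosen as this package's standard
verification scale: 200 selection runs × 500 trees (~5 min on one CPU),
a 20×30 SOM with 10 epochs, 3 replicate cohorts for the classifier
metrics, and 200–400 bootstrap resamples where only CI mechanics are
under test. The `--smoke` CLI profile is smaller still (20 runs, 100
trees) and is a demonstration profile, not the verification scale.

## Known limitations

* The basin extraction automates a visual watershed reading and is
  unreliable on very sparse emergent maps (see above).
* Markers are generated independently; correlated panels may change
  selection stability in ways the tests do not probe.
* The sequential age-then-sex correction is not a joint fit, so
  refitting on corrected data yields slopes that are statistically, not
  identically, zero.
* Medication effects, disease subtypes and assay batch structure are
  out of scope of the generator.
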