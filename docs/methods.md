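# Methods

`grassmilk` implements an indirect surveillance method for grass-based dairy
feeding: because no large-scale grazing calendars exist, the calendar month
of a herd's bulk-milk test serves as an indirect label for whether the cows
were on pasture, and a PLS discriminant model trained on milk-composition
traits learns to recognise the grazing fingerprint itself. The method's
stages, their assumptions, and the numerical choices made in this
implementation are documented here.

## Month-derived labels

In a temperate maritime dairy region, herds graze roughly April–September
with full grazing May–August. Three nested labelling schemes encode this:

| scheme | GRASS months | NOGRASS months |
|--------|--------------|----------------|
| 1      | May–Aug      | Nov–Feb        |
| 2      | Jun–Aug      | Dec–Feb        |
| 3      | Jul–Aug      | Jan–Feb        |

All remaining months are OTHERS (feeding transition) and are excluded from
model fitting. Each scheme has equally many GRASS and NOGRASS months, so
the classes are roughly balanced by construction; scheme 3's sets are
contained in scheme 2's, which are contained in scheme 1's. GRASS is the
positive class everywhere, so reported sensitivity is GRASS recall. The
labels are noisy by design — a confined herd in July is mislabelled GRASS —
which is why external validation accuracy below 100 % is expected even for
a perfect grazing detector.

## PLS discriminant analysis

The classifier is PLS1 regression on a 0/1-coded response, extracted
sequentially NIPALS-style from the mean-centred, unit-variance predictor
matrix. For two classes this is equivalent (up to an affine map of the
prediction) to classical two-dummy-column PLS-DA and produces identical
rankings, ROC curves and VIP orderings. Choices:

* **Autoscaling.** The 48 traits span units from mg/kg to kg/day; without
  unit-variance scaling both the fit and the VIP scores would be dominated
  by the traits with the largest numeric range.
* **Component selection.** The latent-variable count is chosen by 10-fold
  stratified cross-validated AUC over 1..30 components, ties broken toward
  fewer components. The cap of 30 limits over-fitting. One NIPALS fit per
  fold at the cap yields predictions for every smaller count, so selection
  costs one fit per fold, not thirty.
* **Probabilities.** The continuous PLS prediction is mapped to a GRASS
  probability by logistic (Platt-style) calibration on the training scores,
  with regularised targets so the fit stays finite under perfect
  separation. Any strictly monotone map preserves AUC — the selection
  criterion — so this choice affects probability scale only. The NOGRASS
  probability is the complement, and the hard class is the 0.5 threshold.
* **Numerics.** Extraction stops early once the predictor–response
  covariance or score norm falls below 1e−12 (the effective component count
  is recorded); constant predictors are dropped with a warning before
  scaling. Score vectors are orthogonal to 1e−8 and the coefficient vector
  `b = W(PᵀW)⁻¹q` reproduces the component-wise prediction to the same
  tolerance; with as many components as the rank, the fit equals ordinary
  least squares. Duplicated (collinear) predictors are handled without
  failure; predictions agree with a deduplicated fit once extraction has
  run to the effective rank, since both then reach the least-squares
  projection onto the same column space.

**VIP.** Variable importance in projection for predictor *j*:
`VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a )`, with `SS_a = q_a²·t_aᵀt_a`
the response variance explained by component *a*. Mean VIP² over the
predictors is identically 1. Because the interpretive thresholds used here
(50, 60) live on a 0–100 scale, a scaled VIP `100·raw/max(raw)` is reported
alongside. Variable reduction keeps predictors with scaled VIP at or above
the threshold; refitting on the subset is a separate, explicit step, and on
the default synthetic data it costs accuracy relative to the full 48-trait
fit.

## Evaluation protocol

* **Cross-validation.** Stratified 10-fold: within each class the shuffled
  members are dealt round-robin, so fold class proportions are within one
  record of the global proportion. Metrics are reported as mean ± SD over
  folds.
* **AUC** is computed in Mann–Whitney concordance form with average ranks
  (ties count ½), which equals the trapezoidal area under the empirical ROC
  curve exactly.
* **External validation** uses only December/January (truth NOGRASS) and
  July/August (truth GRASS) records from the held-out farms, whatever
  scheme trained the model, so all three models are validated on the same
  footing. Accuracy is the overall fraction correct (not balanced
  accuracy; the protocol set is nearly balanced by construction).
* **Splitting is by farm** (30 % of farms to calibration by default), never
  by record, so herd-level idiosyncrasies cannot leak across sets.

## Meteorology

The temperature–humidity index is
`THI = 0.8·T + (H/100)·(T − 14.4) + 46.4` (T in °C, H in %). Monthly mean
GRASS probabilities (per year × month) are correlated with temperature,
humidity, cloud cover, rain and THI, pooling years into a single series
per trait; cells are aligned on exact (year, month) keys and missing cells
dropped pairwise.

## Farm typology

Farm-year profiles (12 monthly mean probabilities; only farm-years with
all 12 months present) are clustered by Ward agglomeration under the
"Ward.D2" convention: the merge criterion minimises the within-cluster
variance increase computed from unsquared Euclidean distances, via SciPy's
Lance–Williams implementation (`linkage(..., method="ward")`). Merge
heights are nondecreasing; the partition is invariant to profile input
order (exact ties between merge candidates, which do not occur for
continuous profiles, would be resolved by SciPy's internal ordering). The
cluster count K is a configuration parameter (default 12); no automatic
height-gap rule is applied.

Cluster summaries average milk yield, fat, protein and the SFA/MUFA/LCFA
fractions of milk fat (a g/dL trait divided by the fat content, × 100)
over all member records, unweighted. Clusters whose mean fat falls below
1 g/100 g gather skimmed-milk submissions — the altered milk matrix makes
the model's probabilities meaningless there — and are excluded from feeding
interpretation. The remaining clusters are mapped to −1 (intensive) or +1
(extensive); by default clusters below the median annual probability level
are marked intensive, with the intermediate feeding style grouped with
extensive, and the map is configurable because this is an interpretation
step. Summing a farm's yearly values gives the intensity index:
always-intensive (−1 every year), always-extensive (+1 every year), or
intermediate.

## Synthetic data generator

No herd-level bulk-milk dataset with known grazing status is publicly
available at scale, so every stage is exercised on a seeded generator that
emulates one. Per record (farm *f*, year *y*, month *m*):

    g   = amplitude_f · ramp(m) · thi_mod(THI_ym)        (0 in Dec–Feb)
    x_j = baseline_j · (1 + (mult_j − 1)·g) + ε_j

* **Meteorology**: monthly temperature is sinusoidal peaking in July
  (mean 10 °C, amplitude 8 °C, noise SD 1.5 °C); humidity and cloud are
  anti-phased; one series applies to all farms.
* **Grass fraction** `g`: logistic turn-out and housing ramps centred in
  mid-April and early October (default transition width 1.5 months), a
  June–August plateau at the farm's `grass_amplitude`, modulated ±15 % by
  the month's THI (warm months sustain more grass), and forced to 0 in
  December–February.
* **Trait response** is multiplicative in `g` with additive Gaussian noise —
  one interpretable parameter per trait. The default multipliers encode the
  established pasture signatures: C18:3 ×4, conjugated linoleic acid ×2,
  fat and protein ×1.05, milk yield ×0.62, long-chain fatty acids up,
  short/medium-chain down, Ca up and P down. Noise SDs default to the
  published RMSE of each trait's FT-MIR prediction equation, so the
  predictive difficulty is realistic; the 31 fatty-acid residuals share a
  common factor (equicorrelation 0.3) because they are predicted from
  overlapping spectral regions.
* **Baselines** are plausible winter-ration bulk-milk values for
  Holstein-dominated herds (fat 4.05 g/100 g, protein 3.40 g/100 g, milk
  26 kg/day, SFA 2.90 g/dL, ...). No reference herd publishes its means;
  these are documented defaults, not measurements.
* **Archetypes**: intensive (peak grass fraction 0.35), intermediate
  (0.65), extensive (0.95, plus a winter ration itself richer in long-chain
  fatty acids, +0.12 g/dL on the LCFA group), and skimmed (fat stripped to
  ≈0.25 g/100 g; the matrix distortion suppresses the feeding signal in all
  trait means, so skimmed profiles are aseasonal and must be flagged, not
  interpreted). Default cohort mix: 20/35/40/5 %.
* **Fatty acids** are generated on the g/dL-of-milk scale; the g/100 g-fat
  scale used in cluster summaries is derived by dividing by the fat
  content.
* **Determinism**: every farm draws from its own RNG substream keyed by
  (root seed, SHA-256 of farm id), so enlarging a cohort never perturbs
  existing farms; identical configuration and seed reproduce byte-identical
  tables. The latent `g` is stored in the output for test oracles only and
  never enters any model.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: raw FT-MIR spectra and their standardisation
(traits are simulated directly); cow-level within-herd variation and
multiple test days per month (one bulk record per farm-month); systematic
non-grazing seasonality (calving patterns, ration price shifts), so the
null-mode exchangeability of summer and winter is cleaner than reality;
trait cross-correlations beyond the single shared fatty-acid noise factor;
and label noise from farms whose practice contradicts the regional
calendar. Classification on this generator is consequently easier than on
real records — synthetic cross-validated AUCs (~0.99) sit above the level
a field study would report — so results here demonstrate correctness and
qualitative behaviour, not field performance.

## Problem sizes

The analysis drivers and the acceptance script use 200 farms × 3 years
(7200 monthly records, 60 calibration farms), which reproduces every
qualitative behaviour of interest — near-ceiling AUC, the spring/autumn
transition in the probability curve, the THI linkage, and clean typology
recovery — at desk scale. The typology recovery checks use dedicated
cohorts: 60 farms × 2 years at 35/55/10 % intensive/extensive/skimmed for
archetype recovery (K = 3), and 100 farms × 3 years at 10/45/45 %
intensive/intermediate/extensive for the intensity-index fraction.

## Known limitations

* The probability calibration rule of classical PLS-DA software varies
  between implementations (softmax, Bayes posterior, Platt); only the
  monotone-invariant quantities (AUC, rankings) are implementation-
  independent. Probabilities from this package are Platt-calibrated and
  should not be compared numerically with another tool's posteriors.
* VIP uses all fitted latent variables; thresholding at 50 on the 0–100
  scale is an interpretive convention, not a test.
* The intensive/extensive cluster mapping is derived from the clusters'
  probability level by default and should be reviewed against the cluster
  trait summaries before interpretation, exactly as a manual mapping
  would be.
* With K fixed per configuration there is no automatic choice of the
  cluster count; inspect the dendrogram merge heights.
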