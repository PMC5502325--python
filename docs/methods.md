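# Methods

## Cohort model and target

The unit of analysis is a subjects × variables table of mixed-type
measurements (binary, small-integer categorical, continuous) with missing
entries, and a binary target derived by thresholding a symptom score
(label 1 iff score ≥ cutoff; default cutoff 38, the instrument's
high-symptom threshold; the comparison is inclusive). Subjects with a
missing outcome are dropped — the target is never imputed. Variable kinds
are inferred from observed values (≤2 levels binary, ≤10 integer levels
categorical, otherwise continuous) and can be overridden in a sidecar
config; the file reader treats empty cells, `NA` and `NaN` as missing
(configurable), and rejects duplicate column names and ragged rows outright.

## Preprocessing

Order is filter → impute → normalize.

* **Missingness filter**: variables missing in strictly more than a
  threshold fraction of subjects (default 0.5) are eliminated. The filter
  uses no outcome information, so it is applied once to the full table
  without leakage.
* **kNN imputation** (unsupervised; the outcome is never an input): each
  missing cell is filled with the plain mean (optionally inverse-distance
  weighted) of that variable over the k nearest donors, k = 10 by default.
  Distance is the mean squared difference over mutually observed
  coordinates — averaging rather than summing keeps donors with different
  overlap sizes comparable; donors with no overlap or no observed value in
  the needed variable are excluded (falling back to the donor column mean
  if none remain). Imputed binary/categorical values are rounded to the
  nearest observed level so downstream contingency tests stay valid. When a
  table is imputed against itself each subject's own row is excluded from
  its donor pool.
* **0–1 normalization**: x ↦ (x − min)/(max − min) per variable; constant
  variables map to zero with a warning. Bounds are stored so the same
  affine map can be applied to held-out data, where values are deliberately
  *not* clipped to [0, 1].

Inside cross-validation, imputation donors and normalization bounds are
refit on each outer training fold and applied unchanged to its test fold.
Whether normalization preceded or followed imputation in the original
protocol is not documented; this package imputes on the raw scale and
normalizes afterwards, and both stages are per-fold.

## Conditional-independence testing

HITON-PC consumes a single primitive: a test of x ⟂ y | Z on complete data.

* All-discrete triples: the G² likelihood-ratio statistic,
  2·Σ O·ln(O/E) summed over the cells of every conditioning stratum, with
  (|x|−1)(|y|−1)·∏|z| degrees of freedom against a chi-square tail.
* Anything involving a continuous variable: Fisher's z-test of the partial
  correlation (residualize x and y on Z with an intercept, correlate the
  residuals, statistic √(n−|Z|−3)·atanh(r)). Discrete variables enter
  numerically; a forced all-discrete mode median-splits continuous
  variables instead.

Each result carries a reliability flag — discrete tests require an average
expected cell count ≥ 5 (n / number of cells), continuous tests an
effective sample n − |Z| − 3 ≥ 10 — and an unreliable test never rejects
independence. This is the standard small-sample guard in constraint-based
discovery: at n = 163 a deep conditioning set can otherwise "separate"
anything. Significance level alpha defaults to 0.05. Zero-variance inputs
return p = 1, unreliable.

## Semi-interleaved HITON-PC (no symmetry correction)

1. Rank variables by univariate association with the target; keep p ≤ alpha
   (ties: ascending p, then descending |statistic|, then name — the
   protocol is deterministic given data and parameters).
2. Pop candidates strongest-first into a tentative PC set; each new
   candidate is immediately tested against the target conditioned on every
   subset of the previously admitted variables up to size max_k
   (default 3), subsets enumerated smallest-first so the cheapest
   separating witness is recorded; a separated candidate is discarded
   permanently with its witness.
3. After the open list empties, a backward pass re-tests every member
   against subsets of the other current members and removes any that
   separate.

No reciprocal-membership (AND) correction is applied. Because the target
here is terminal — it has no children, hence no spouses — the PC set equals
the Markov boundary, so no spouse-recovery phase is implemented. On null
data the selection is not empty but sits at the false-positive level:
roughly alpha·p variables pass the univariate filter and most survive
conditioning (conditioning on other null variables barely moves their
p-values), a property the tests assert quantitatively.

## Classifier families and scoring

Seven families behind one contract (fit on training data, return a
continuous case-likeness score per test subject, never touching test
labels): linear/polynomial/RBF SVM (margin scores), random forest
(predicted class fraction over trees, seed-controlled), lasso-penalized
logistic regression, plain logistic regression (probability scores), and
stepwise logistic regression — a classic forward-backward hill-climb on
AIC. The stepwise criterion is fitted by Newton/IRLS; quasi-separation
(exploding coefficients) falls back to a ridge-stabilized fit with a
warning. With many candidates, a vectorized Rao score test pre-screens the
forward step and exact AIC is evaluated on the top ten — the score and
likelihood-ratio orderings agree to first order, and with ≤ 16 candidates
the search is exact.

Class imbalance: at 11 cases in 163 subjects the margin and GLM families
use inverse-prevalence class weighting by default (without it they
degenerate to the majority class); the forest is left unweighted.

Hyperparameter grids (the original study reports none): SVM C ∈
{0.01,…,100}, RBF gamma ∈ {0.01,…,10}, polynomial degree ∈ {2,3}, forest
with 500 trees × two feature-subsampling rates, lasso C on a 20-point log
grid. Simulation studies and permutation reruns use reduced grids
(`small_grid`) — two points per SVM/lasso family and a 100-tree forest —
chosen once as the package's simulation-scale defaults.

AUC is the Mann–Whitney statistic (probability that a random case outscores
a random control, ties ½), computed by scikit-learn and cross-checked
against explicit pair enumeration in the tests.

## Repeated nested cross-validation

Each repeat partitions subjects into N = 5 stratified folds (an 80/20 split
used five times, every subject held out exactly once; stratification is
essential — unstratified folds at 7% prevalence frequently contain no
cases). Within each outer training set an inner (N−1)-fold loop picks the
grid point with the best pooled inner AUC (ties to the earliest grid
point). Feature selection, when active, runs inside each outer training
fold. The per-repeat estimate pools all held-out scores into one ROC —
with 2–3 cases per fold, per-fold AUCs are too unstable — and the reported
estimate is the mean ± SD across repeats.

**Pooling on within-fold midranks.** Raw score pooling across folds is
measurably pessimistic under the null for probability-scaled families
(fold models have incompatible score offsets, and stratification couples a
fold's training prevalence to its test composition; the random-forest null
mean lands near 0.47). Each fold's test scores are therefore replaced by
their within-fold midranks (scaled to (0,1)) before pooling: under label
exchangeability the case ranks are uniform within every fold, so the
pooled-rank AUC has mean exactly 0.5 under the null, while cross-fold
comparability no longer depends on the model's score scale. Raw pooling
remains available (`pooling='scores'`).

The inner loop reuses the outer-training-fold preprocessing rather than
re-imputing inside every inner split; this can only affect which
hyperparameter wins, never the outer estimate, and keeps the protocol
tractable.

## Label shuffling and bootstrap stability

The permutation test redraws a uniform permutation of the labels (class
counts exactly preserved) and reruns the full protocol per shuffle; the
p-value uses the add-one estimator p = (1 + #{null ≥ observed})/(1 + B), so
p > 0 always. Permutation reruns default to 5 outer repeats instead of 30 —
the null mean is invariant to the repeat count, and 400 full-fidelity
reruns are rarely affordable — with a full-fidelity option. The null mean's
distance from 0.5 is reported as the protocol-bias estimate.

Stability: B = 100 bootstrap resamples of size n, stratified by class
(avoiding one-class resamples at 7% prevalence; unstratified available),
HITON-PC per resample, per-variable selection counts, and a stable set by
strict threshold (> 20 of 100). Ranking is by descending frequency with
lexicographic tie-break. Two caveats the synthetic experiments make
explicit: near-duplicate informative variables split their selection
frequency (information overlap), and a noise variable spuriously associated
with the outcome *in the cohort at hand* stays associated in most resamples
— bootstrap stability protects against resampling variability, not against
cohort-level spurious association.

## Synthetic cohorts

`SyntheticSpec` defaults emulate the study conditions: 163 subjects, 105
variables (40% binary, 20% categorical, 40% continuous), 5 planted parents
with log-odds effects (0.78, 0.65, 0.52, 0.46, 0.39) per SD of the
standardized parent — calibrated once so the Bayes-optimal AUC of the true
linear predictor is ≈ 0.80, the performance regime of the reference study —
a logistic link whose intercept is solved by bisection on a 200 000-draw
Monte-Carlo sample to hit 7% marginal prevalence (tolerance < 0.002), 10
distractors that are noisy copies of parents at correlation 0.7
(conditionally independent of the target given their parent, so the true
PC set stays the parent set), completely-at-random missingness at 5%, and 5
noise columns forced above 50% missingness. High-missingness columns are
drawn from the noise block so the planted structure survives the filter.
The Bayes AUC is estimated by Monte-Carlo from the true linear predictor
(Hanley–McNeil standard error reported) and is cross-checked against direct
numeric integration of the two class-conditional score densities in the
tests.

What the generator does **not** emulate: the real variables' marginal
distributions, linkage among genotype variables, informative missingness,
and outcome measurement error. Passing tests therefore demonstrate protocol
correctness (calibration, unbiasedness, recovery under the stated model),
not clinical performance on real data.

## Problem sizes in tests and drivers

Simulation-scale defaults were chosen as the package's own study sizes: the
null-calibration experiment uses 30 replicate noise cohorts × 2 repeats;
recovery uses 20 replicates at n = 5000 (exactness) and 30 per sample size
for the F1 trend; sufficiency uses 10 cohorts × 5 repeats; the analysis
drivers use 5 outer repeats and 50 permutations. The reference protocol's
30 repeats / 400 permutations / full grids remain the library defaults for
real analyses.

## Known limitations

* Exact reproduction of the reference study's Table-1 numbers is not
  possible from the protocol description alone: the CI test, alpha, max_k,
  classifier grids and class-weighting choices are unstated there; all are
  exposed in config here.
* The Fisher-z test on a binary target is an approximation (the latent
  linear model is misspecified for Bernoulli outcomes); it is the standard
  mixed-data instantiation and behaves well in the calibration tests.
* At fixed alpha, constraint-based selection retains each correlated
  distractor with probability ≈ alpha per effective conditioning test;
  exact-set recovery probabilities degrade accordingly as distractor count
  grows. This is a property of the algorithm family, not of the
  implementation.
* AIC-based stepwise selection with a wide candidate pool overfits by
  construction (many chance improvements beat the +2 penalty); it is
  included as the conventional baseline the modern protocol is compared
  against.
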