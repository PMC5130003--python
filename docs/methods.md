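# Methods

## Model and procedure

`psvmatch` implements signature-based personalized prognosis in four
stages.

**1. Survival-driven binarization (1D-DDg).** For each continuous variable
the cohort is split at a candidate cutoff — a midpoint between consecutive
distinct sorted values — such that both sides retain at least
⌈`min_group_frac` · N⌉ patients. The split minimizing the 2-group log-rank
p-value wins (ties go to the lowest cutoff, deterministically). A
one-covariate Cox partial-likelihood Wald statistic (Breslow ties, Newton
iterations, |β| capped at 20) is available as an alternative objective via
`statistic="wald"`. The side whose O/E hazard ratio exceeds 1 is labelled
high risk, so every fitted rule has hazard ratio ≥ 1; values exactly at the
cutoff belong to the "≤" (low-value) side. The variable's weight is
−log₁₀ p, with p floored at 1e−300 so weights stay finite. The final
p-value and hazard ratio of each rule are recomputed through the public
`logrank_test` / `hazard_ratio` functions, so re-splitting the training
cohort at the stored cutoff reproduces the stored numbers bit-for-bit.
The number of cutoffs searched is stored per variable: the minimized
p-values are reported raw (no multiplicity correction), and downstream
users can correct for the recorded search size if they need calibrated
per-variable significance.

**2. Vector construction.** Variables are ordered by descending weight
(ties: higher hazard ratio, then lexicographic id). Per patient, the binary
profile G (1 = low, 2 = high) is centered to D = 2(G − 1.5), weighted to
A = diag(W)·D, and accumulated to the prognostic signature vector
V (prefix sums of A). The scalar average weighted risk is
AWR = ΣwᵢGᵢ/Σwᵢ ∈ [1, 2]; algebraically AWR = 1.5 + Vₙ/(2Σw), which the
test suite uses as a cross-check oracle. A query patient missing a
variable's value receives the training-cohort majority risk for that
variable (flagged in the returned vectors); queries missing more than 20%
of the signature are refused. Majority ties resolve to low risk.

**3. Reference stratification.** The training cohort's AWR axis is cut into
k groups (default 3: low / intermediate / high) by exhaustive search over
all (k−1)-tuples of cutpoints lying between distinct sorted AWR values,
each group at least ⌈`min_group_frac` · N⌉ patients, maximizing the
k-group log-rank statistic. This is an AWR-cutpoint simplification of
statistically weighted voting grouping, and is recorded in the model file
as `method = "awr-cutpoint"`. Group membership depends only on a patient's
AWR value, so labels are invariant to input order. Equal-sized AWR
quantile grouping (`quantile_group`, remainder patients assigned to the
lowest-AWR groups, boundary ties broken by patient id) is provided for
descriptive displays.

**4. Matching and prediction.** A query is scored against every reference
in PSV space (recommended), PBVV space, or raw post-alignment values,
under Euclidean distance, Kendall tau-b (tie-corrected; required because
binary profiles are tie-dense), or ridge-regularized Mahalanobis distance
(λ = 1e−6·tr(Σ)/n; retained as a negative-result baseline — cumulative
sums give the PSV a strongly increasing variance profile and a
near-singular covariance). Prediction modes: nearest reference, majority
of the top k ∈ {1, 5, 9, 13, 17} (tied votes fall back to the single
nearest), or closest per-group median centroid. Exact similarity ties are
broken by the smaller |AWR_query − AWR_ref|, then reference id — AWR is
the method's own risk proxy, so it is the natural deterministic arbiter.

## Survival primitives

Kaplan–Meier, Nelson–Aalen (H(t) = Σ d/n), the k-group log-rank test and
the O/E hazard ratio are computed from one shared "prefix partition"
table: with patients arranged along an axis, the observed/expected/variance
quantities of every contiguous split derive from cumulative at-risk counts,
and the bilinear variance terms for k ≥ 3 reduce to one matrix product.
Every candidate cutpoint set is then scored in O(1), which is what makes
the exhaustive searches above affordable (a full 3-group stratification of
400 patients scores ~45 000 cutpoint pairs in well under a second).
Censored observations at time t remain at risk for events at t. The test
suite checks all of these against lifelines and against brute-force O/E
accumulations. Kernel-smoothed hazard curves (Epanechnikov, bandwidth =
follow-up range / 10) are display-only.

## Cross-cohort alignment

Query cohorts are aligned to the reference by shifting each shared
variable by (reference mean − query mean). This per-variable mean
alignment is idempotent, leaves the reference untouched, and is the
package's stand-in for batch correction; it captures constant per-cohort
offsets only, not variance or covariance batch structure.

## Evaluation machinery

*Similarity–AWR diagnostic.* For a fixed query, similarities to all
references are min–max rescaled to [0, 1] and least-squares fitted as a
quadratic in reference AWR; the RMS residual measures how well-structured
the similarity-vs-risk relationship is (a prognostically meaningful
measure is most similar near the query's own risk level and decays toward
both extremes).

*Cross-validation.* Patients are partitioned at random (seeded) into 10
folds; per fold the signature and reference groups are refit on the other
folds and held-out patients are predicted by nearest-reference matching.
Ground truth is the label from a single full-cohort fit (held-out patients
have no other defined label); accuracy is reported as mean ± SD over
folds. Folds whose training side cannot be stratified are skipped; more
than two skipped folds abort.

*Association statistics.* Cohen's weighted kappa uses quadratic weights
1 − ((i−j)/(k−1))² by default — the variant that reproduces the published
coefficients 0.1501 and 0.183 on the shipped contingency tables (linear
and unweighted variants do not, giving ≈0.104/0.070 on the first table) —
with a fixed-margin permutation p-value (scipy `random_table`, 10 000
draws by default), since the asymptotic variant used by the source is
unstated. Pearson chi-square is computed without continuity correction.

*Permutation calibrations.* Two are provided. `stratification_permutation_p`
re-optimizes the AWR cutpoints on permuted risk-to-survival pairings and
calibrates the optimism of the cutpoint search for a *fixed* risk score.
`pipeline_permutation_p` reruns the **entire** pipeline (DDg refit
included) per permutation: because cutoffs and cutpoints are optimized on
the same survival data, the in-sample stratification statistic is
optimistic even for pure-noise variables, and only the full-pipeline null
is exchangeable with the observed statistic.

## Synthetic cohorts

The generator plants k latent risk groups (default proportions ⅓/⅓/⅓ over
400 patients). Informative variables (20 of 37 by default) are unit-SD
Gaussian with a mean shift of `effect_size` (default 2) per group step and
a random sign per variable, so high expression may be adverse or
protective and the direction-detection logic is exercised; remaining
variables are pure noise. Age is Gaussian (SD 10) around 60 plus 4 years
per group step, floored at 30. Event times are exponential with rate
0.02 × group hazard ratio (defaults 1/2/4; low-group median ≈ 35 time
units, in the range of ovarian-cancer overall survival in months); a
Weibull shape parameter is accepted for robustness checks. Independent
exponential censoring is calibrated — analytically for the exponential
case, by quadrature for Weibull — so the expected censored fraction equals
`censoring_rate` (default 0.3). Which variables are informative, and their
shift signs, are drawn from a separate `structure_seed`, so cohorts
differing only in `seed` (train/test pairs) share their ground-truth
design. The generator does **not** emulate probe-level microarray noise,
batch structure beyond a constant shift, or covariate-dependent censoring;
passing tests demonstrate the machinery recovers planted structure, not
performance on real cohorts.

Problem sizes used by the shipped tests: full-pipeline runs at n = 400
(20 replicates), measure-comparison runs at n = 300 (20 replicates,
25 queries per replicate, 10-fold CV), null calibrations at n = 150 with
15 variables and 99 permutations. The whole suite completes in about two
minutes on one CPU.

## Numerical choices

- Weights: p-values floored at 1e−300; weight = −log₁₀ p.
- Cutoffs: midpoints of consecutive distinct values; statistic ties keep
  the first (lowest) candidate.
- Mahalanobis ridge: λ = 1e−6·tr(Σ)/n.
- Kendall: tau-b; bulk ranking returns NaN for constant vectors
  (undefined correlation), and NaN-scored references sort last.
- Model files: single JSON document, schema-tagged and versioned, floats
  at full double precision.
- Comparisons against the shipped printed tables round half away from
  zero to 3 decimals.

## Known limitations

- **In-sample optimism of cutoff-optimized stratification.** Both the
  per-variable cutoffs and the AWR cutpoints are optimized on the training
  survival data. The borderline classifications this produces are
  survival-aligned *in sample*, so within-group AWR ordering carries
  spurious signal that the cutpoint search then exploits; reference group
  boundaries can shift substantially away from the latent structure even
  when the AWR itself separates groups almost perfectly. Out of sample
  the effect disappears, which is precisely why `pipeline_permutation_p`
  must refit everything per permutation. Consequences: reference labels
  (and therefore query predictions and cross-validated accuracy against a
  full-fit ground truth) are noticeably noisier than the AWR score itself,
  especially when adjacent groups differ by a hazard ratio of only ~2 and
  the multi-group log-rank surface is nearly flat in the middle boundary.
  Users wanting latent-structure recovery rather than maximal in-sample
  separation should prefer larger cohorts, stronger hazard separation, or
  quantile grouping of the AWR.
- **Printed-table rounding.** The shipped worked-example table's
  cumulative column was computed by its source from unrounded weights with
  each cell rounded independently; running sums of the printed 3-decimal
  weights reproduce the adjustment column exactly but deviate from the
  printed cumulative cells by up to 0.003.
- The per-variable mean alignment is not a batch-effect model; k-group
  stratification above k = 3 grows combinatorially (k = 5 is admissible
  but slow); the Wald objective is available for per-variable
  binarization only, not for the multi-group cutpoint search.
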