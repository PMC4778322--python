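# Methods

## Problem and data model

A candidate ubiquitination site is a lysine (K) in a protein sequence; the
unit of analysis is the odd-length window of `w` residues centered on it
(default `w = 27`; `w = 13` and any odd `w >= 3` are accepted).  Windows
that overrun a protein end are padded with `-`.  Coordinates are 1-based,
and annotated positive positions are validated to point at a K.  Duplicate
windows (e.g. from homologous proteins) are kept; the pipeline performs no
redundancy filtering.

Features come from an AAindex1 property database: each retained entry
assigns one real value to each of the 20 amino acids, and entries with any
missing (`NA`) value are dropped rather than imputed (with the full AAindex
release this retains 531 of 544 entries; the filter is driven by the data,
not hard-coded).  The feature value of a segment for a property is the
arithmetic mean of the property over the segment's *standard* residues.
Gaps and non-standard letters (B, J, O, U, X, Z) contribute to neither
numerator nor denominator — treating `-` as a zero-valued residue would
make features depend on how much padding a window happens to carry, which
is an artifact of protein length rather than biology.  Extraction itself is
lossless: non-standard letters stay in the segment string and are only
excluded at featurization.

For the discrete classifiers every feature column is cut into `n_bins = 3`
equal-width intervals over its observed range; bins are left-closed and
right-open except the top bin, which is closed, so every value including
the maximum is assigned.  A constant column maps to bin 0.  The bin edges
are by default fitted on the full dataset before cross-validation, which
mirrors how such pipelines usually discretize once up front; because the
edges use only the unlabelled feature marginals, the leakage this admits is
mild, but a `refit_discretization` switch re-fits edges per training fold
for a strictly leakage-free run (out-of-range test values are clipped into
the end bins).

## Discrete scoring machinery

All Bayesian classifiers operate on families (child variable, parent set)
with *declared* arities — 3 for features, 2 for the target — so states
unseen in a training fold still occupy CPT rows.  Parent configurations are
indexed in mixed-radix order (first parent most significant); count tables
are sparse, and an unobserved configuration contributes exactly zero to
either score, keeping scores computable when the configuration space is
combinatorially large.

* K2 (Cooper–Herskovits) log score:
  `sum_j [ ln (r-1)! - ln (N_j + r - 1)! + sum_k ln N_jk! ]`,
  the marginal likelihood under unit Dirichlet priors.
* BDeu log score with equivalent sample size `ess` (default 1.0, never
  dictated by the data):
  `sum_j [ lnΓ(α_j) - lnΓ(α_j + N_j) + sum_k ( lnΓ(α_jk + N_jk) - lnΓ(α_jk) ) ]`
  with `α_jk = ess/(q·r)`, `α_j = ess/q`; satisfies likelihood equivalence,
  which the tests verify on two-variable structures.

CPTs are Dirichlet-smoothed, `P(k|j) = (N_jk + a)/(N_j + r·a)` with
pseudocount `a = 1` (Laplace) by default; `a = 0` with an unobserved parent
configuration is an error rather than a silent NaN.  All arithmetic is in
natural-log space via log-gamma.

## Classifiers

**NB.**  `P(t|x) ∝ P(t) · Π_i P(x_i|t)`, normalized; the posterior
probability of class 1 is the ranking score everywhere.

**FSNB.**  Greedy forward selection maximizing the total network score
(family score of the target plus all feature families) under the NB
structure, K2-scored by default.  Because the score decomposes over
families and a candidate's family (feature with parent T) is unaffected by
the other selections, each feature's gain `score(X_i|{T}) - score(X_i|∅)`
is a constant of the data, and the greedy order is exactly the descending
order of positive gains (ties broken by column order, making fits
reproducible).  The recorded score trace is strictly increasing and the
search stops when no gain is positive.

**MANB.**  Exact Bayesian model averaging over all 2^n feature-inclusion
subsets with an independent prior `arc_prior = 0.5` per arc (uniform over
subsets).  Averaging the subset-model *joints* weighted by
prior × marginal likelihood factorizes per feature, giving arc-posterior
weights `w_i = σ(logit(arc_prior) + m1_i - m0_i)` (computed stably in log
space) and the O(n) posterior
`P(t|x) ∝ P(t) · Π_i [ w_i P(x_i|t) + (1-w_i) P(x_i) ]`.
The test suite checks this against explicit 2^n enumeration to 1e-9 —
note that averaging subset *posteriors* instead of joints would not
factorize and is not what exact model averaging computes.

**EBMC.**  A greedy target-centric structure search under BDeu:

1. *Phase A* grows the set of variables that best predict the target,
   scored as a candidate parent set of T via the target family score
   (BDeu of T given the set), accepting only strict improvements.
2. On stall the set is converted to the statistically equivalent form in
   which the variables are children of T.  Exact equivalence requires
   chain arcs among the children (child j is conditioned on T *and* the
   earlier children): a naive children-of-T form would assert conditional
   independence among the predictors that the parents-of-T form does not,
   and would change the fitted posteriors.  With maximum-likelihood CPTs
   both factorizations give identical training posteriors (verified to
   1e-9), because both reduce to the empirical conditional of T given the
   selected variables.
3. *Phase B* grows a separate set of true parents of T (bounded by
   `max_parents = 2`, since unbounded parent sets explode the T-CPT;
   configurable), again by strict BDeu improvement of the target family.
4. Phases alternate until neither adds a variable.

Prediction: `P(t|x) ∝ P(t|x_Pa) · Π_j P(x_cj | t, x_c1..c(j-1))`, the class
prior replacing the first factor when no parents were selected.  Chain
growth is additionally capped when the next child's CPT would exceed a
dense-table limit; in practice the strict-improvement rule stalls long
before that.

**Linear baselines.**  All three consume per-training-fold standardized
features (mean 0 / variance 1; zero-variance columns map to zeros) — the
conventional prerequisite for penalized and weighted linear fits.  Class
weights are inverse-frequency, `cw(c) = N/(2 N_c)`, applied to LR and SVM;
the weights are identically 1 on balanced data, so "auto" weighting is
harmless there and counteracts the majority class otherwise.  LASSO is an
unweighted squared-error fit of the 0/1 label (which is why it collapses
to near-constant predictions, AUROC 0.5, on strongly unbalanced data — the
behaviour the benchmark table shows for the unbalanced sets).

* LR: class-weighted maximum likelihood (lbfgs), optional small ridge for
  stability (`ridge = 1e-8` by default, i.e. effectively the MLE);
  non-convergence raises with diagnostics rather than returning silently.
* SVM: hinge-loss linear SVC (`C = 1`); the signed distance to the
  hyperplane is the ranking score.
* LASSO: either a fixed L1 bound `s` solved exactly on the LARS path
  (piecewise-linear interpolation between knots; `s = 0` is the
  intercept-only fit), a fixed penalty λ (coordinate descent), or — the
  default — a λ grid spanning three decades below the data-derived
  `λ_max = max|X'(y - ȳ)|/n`, selected by inner stratified 3-fold CV on
  training-fold AUROC.  The intercept is never penalized.

## Evaluation

Stratified k-fold CV (default k = 5, fold-shuffle seed 42 recorded in every
result): each class is shuffled by a seeded generator and dealt round-robin,
so per-fold class counts deviate from proportionality by at most one.
AUROC is the average-rank Mann–Whitney statistic (exact, O(n log n), ties
half-credited), identical to the trapezoidal ROC area.  Sensitivity at
fixed FPR is the TPR at the strictest threshold whose FPR does not exceed
the target.

Method comparison across datasets uses outperformance percent
(`mean_d 100·(a_d - b_d)/b_d`) and a paired two-sided t-test with datasets
as the pairing unit.  Feeding the published seven-method × six-dataset
AUROC table through these reproduces the published comparison cells for
every group whose printed 4-decimal inputs determine the result ("All",
"UnBalanced", "Large-scale" — e.g. EBMC over NB by 20.12 %, p = 0.0007).
The "Balanced"-group cells and the EBMC:SVM "All" cell do not reproduce
from the printed values (rounded inputs give e.g. 25.99 vs the printed
25.87, and 2.71 vs 2.77), indicating they were computed from unrounded
per-fold AUROCs; those cells are therefore documented as out of reach of
the printed inputs and excluded from the reproduction checks.

## Synthetic data: what it does and does not emulate

The generator's defaults are the package's study conditions: 500 segments,
window 27, balanced classes, 3 informative properties out of a 40-entry
property file (10 % of entries carrying an NA, leaving 36 usable — enough
features for the structure searches to have real competition at a cost that
keeps the full seven-method benchmark in seconds), enrichment `delta = 0.8`.
Negative flanks draw residues i.i.d. from a background distribution
(uniform over the 20 codes by default; a natural-abundance table can be
supplied).  Positive flanks draw, with probability `delta`, a residue
uniformly from the 10 top-valued residues of a uniformly chosen informative
property, otherwise from the background.  This plants a mean shift in the
informative properties' segment averages that grows with `delta`, giving a
clean detectability dial: at `delta = 0` the classes are identically
distributed and all methods sit near AUROC 0.5; at `delta = 0.8` all seven
methods exceed 0.7 and the Bayesian structure searches recover planted
properties in nearly every replicate.

What the generator does *not* emulate: positional structure (real
ubiquitination motifs are position-specific; the planted signal is
exchangeable across flank positions), residue correlations within a
segment, homology between segments, the extreme class imbalance of real
proteome-wide data, and the correlation structure of real AAindex entries
(many published properties are near-duplicates).  Passing the
signal-recovery suite therefore demonstrates that the estimators and the
harness are correct, not that any particular AUROC is attainable on real
proteins.

## Numerical and design notes

* Greedy ties everywhere break toward the lowest column index; fits are
  deterministic functions of (data, config, seed).
* FSNB scores with K2 and EBMC with BDeu by default (each search is
  conventionally paired with that score); both are configurable.
* Posteriors are computed in log space and normalized by logsumexp; CPT
  smoothing keeps every factor strictly positive, so no log(0) arises with
  the default pseudocount.
* The AUROC of a constant score vector is exactly 0.5 by the tie rule —
  relevant for LASSO at `s = 0` and for empty Bayesian models.
* Degenerate inputs fail loudly: single-class labels, segments with no
  standard residue, annotations not pointing at a K, malformed AAindex1
  entries, `ess <= 0`, arc priors outside (0, 1).
* Test and acceptance problem sizes (300–500 segments, 36 properties, 10
  replicates) were chosen so the full suite runs in seconds while keeping
  the null AUROC band and recovery rates stable across seeds.

## Known limitations

* The EBMC search is the package's documented reading of a greedy
  parents-then-convert-then-parents scheme; other interleavings of the two
  phases are possible and could select slightly different structures.
* Full-data discretization (the default) leaks feature marginals across
  folds; use `refit_discretization` when that matters.
* The LASSO L1-bound mode interpolates the LARS path, which assumes the
  standard general-position conditions on the design.
* No homology reduction, no position-specific features, no calibration of
  posterior probabilities (only their ranking is consumed by AUROC).
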