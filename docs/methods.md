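# Methods

This note records the models implemented in `hccdx`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical corner cases. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The package targets binary one-year survival classification of
hepatocellular-carcinoma patients from a small clinical table: the
reference layout is 165 patients × 49 features (23 dichotomous risk
factors and findings, 3 ordinal severity grades, 23 ratio-scaled
laboratory/demographic measurements), with label 0 = dies, 1 = lives
(63/102). About 10 % of cells are missing and almost no row is complete,
so imputation is a first-class concern. The built-in schema reproduces
the published summary table verbatim, including its implausible units
(e.g. Leukocytes "2.2–13000", Platelets "1.71–459000"); correcting the
source is out of scope, and nothing downstream depends on units.

## Preprocessing

Six imputers are provided: per-feature **mean**, **median** (average of
the two middle observed values at even counts), **highest** (maximum
observed), constant **zero**, constant **ones**, and **iterative**. The
iterative scheme initializes missing cells at the feature means, then
cycles round-robin over incomplete features, regressing each on all
others by ordinary least squares over its observed rows and re-predicting
its missing cells. Defaults: at most 10 rounds, early stop when no
imputed cell moves by more than 1e-3; both configurable
(`impute.max_rounds`, `impute.tol`). The iteration contracts to the OLS
fixed point; a short transient (one or two rounds) can precede monotone
decay, which is why the convergence test checks decay after the
transient rather than strict monotonicity from round one.

After any fill, dichotomous/ordinal features are rounded **half-up** to
the nearest admissible integer in range (when a schema is attached), so
category codes stay categorical; mean/median/iterative would otherwise
produce fractional categories. Default imputer is **median**: among the
statistic-based fills it is the most robust to the heavy-tailed
laboratory values this kind of table contains.

Normalization is the z-score z = (x − μ)/σ with **population** SD
(ddof = 0; `normalize.sd_convention` switches to sample SD). Outputs are
unbounded standardized values — the common claim that z-scoring maps to
[0, 1] is simply false and is not implemented. Zero-variance features map
to all-zero columns. The normalizer refuses tables that still contain
masked cells: the pipeline order is impute → normalize, enforced.

**Leakage.** The default evaluation mode preprocesses (and, when enabled,
selects features) once on the full table before cross-validation. This
mirrors the flowchart-style protocol common in this literature and is
therefore the default, but it leaks test information into the imputer,
the normalizer and the selected mask; `leakage_mode="strict"` refits all
of them on each training split and is the defensible choice for honest
generalization estimates. Expect strict-mode scores to be lower.

## Gain-ratio decision trees

Entropy is Shannon entropy in bits, H(S) = −Σ_c p(c) log2 p(c) with
0·log 0 = 0 (the minus sign is required for the non-negativity of
information gain). Residual entropy of a split is Σ_a p(a)·H(S|a) over
non-empty branches; gain = H − residual; split information
−Σ_a p(a) log2 p(a); gain ratio = gain / split information, defined as 0
when split information vanishes (including one-branch splits).

Ratio features split by binary thresholds at **midpoints between
consecutive distinct sorted values** (the C4.5 convention); qualitative
features split one branch per observed category (admissible only when at
least two branches meet `min_leaf`). The default criterion is
**gain_ratio** — matching the C4.5 lineage — with plain `gain` available.
Growth stops on purity, `min_leaf` (default 2), `max_depth` (default
unlimited), or when no split has positive criterion. Ties break to the
lowest feature index, then the lowest threshold; identical inputs give
bit-identical trees. After z-scoring, all pipeline features are treated
as ratio-scaled (the category codes remain discrete values, so threshold
splits express the same partitions).

Pruning is pessimistic error-based, bottom-up: a subtree collapses to a
leaf when n·U_CF(E, n), the binomial upper-confidence bound on its
training errors as a leaf, does not exceed the sum of its children's
estimates. Default confidence 0.25 (the conventional C4.5 value),
toggleable; whether the reference experiments pruned is unknowable, so
both paths are first-class. Prediction descends deterministically; an
unseen category routes to the child with the largest training count.

## Harris Hawks Optimization

The continuous optimizer follows the canonical population loop: per
iteration, a fitness sweep over all N hawks updates the rabbit (the
best-ever position — greedy, so the best-so-far trace is
non-increasing), then each hawk moves. Per hawk, E0 ~ U(−1, 1) and jump
strength J = 2(1 − r) are redrawn each iteration; E = 2·E0·(1 − t/T).
|E| ≥ 1 triggers the exploration move (random-hawk perch or
rabbit/mean/bounds move, one uniform q deciding); |E| < 1 selects among
soft besiege, hard besiege, and their rapid-dive variants by (|E| ≥ 0.5,
r ≥ 0.5). Dive variants probe Y (the besiege step; the hard variant uses
the population mean) and Z = Y + S·LF(D) with S ~ U(0,1)^D, accepting a
candidate only if it improves the hawk's own fitness, else the hawk stays
put. Moves are scored at the next sweep; the final iteration's moves are
never evaluated, so a one-iteration run returns the best of the initial
random population exactly.

Levy flights use the Mantegna construction, β = 1.5, step scale 0.01 —
the convention of the original HHO publication. Note the Mantegna step's
variance does not tend to a matched normal's as β → 2 (σ_u ∝
sin(πβ/2)^{1/β} → 0); what β controls is tail mass, and the tests assert
exactly that (heavier tails at smaller β, ~10 % of |steps| beyond the
matched normal's 99th percentile at β = 1.5).

Out-of-box positions are clipped to [LB, UB] (reflection available). A
non-finite objective value raises immediately, naming the position.
Defaults for feature selection: N = 30 hawks, T = 100 iterations.

## Binary wrapper feature selection

Continuous positions live in [−4, 4]^m — wide enough that the V-shaped
transfer value spans ≈ [0, 0.84], so bits can both saturate and stay
undecided. Binarization draws **per-dimension i.i.d. thresholds**
(the standard reading for V-shaped binarization; a single shared
threshold is available behind `shared_threshold`). An all-zero mask is
repaired by forcing one uniformly chosen bit — a penalty-free degeneracy
rule that never stalls the optimizer on an empty subset.

Subset fitness is the pooled out-of-fold MSE of the configured classifier
restricted to the mask, under internal stratified k-fold CV. Predictions
are hard labels, so MSE = misclassification rate = 1 − accuracy exactly.
Folds and bag seeds derive from the configuration seed only, making a
mask's score deterministic: scores are cached by bitstring and a mask is
never re-evaluated, and the score is invariant to consistent column
permutations. The default fitness classifier is the bagged meta-ensemble
with 10 internal folds (the same model family the pipeline deploys). The
ensemble fitness matters for recovery, not just deployment-fidelity:
its four bags grow diverse trees whose union uses more of the informative
features, so masks that drop an informative feature score visibly worse —
a single-tree fitness plateaus once two or three informative features are
present and recovers the rest much less reliably. The recovery studies in
the test suite and acceptance script therefore keep the ensemble fitness
and economize elsewhere: 3 internal folds, trees capped at depth 6, and
N = 15 hawks for T = 30 iterations. A still-faster single-tree mode
(`fitness_mode="tree"`) remains available for interactive exploration.
The selector returns the best mask over *all* evaluations, not the final
rabbit.

## Bagged meta-ensemble

Default Z = 4 bags by **stratified disjoint partition** (class members
shuffled and dealt round-robin, so bags are near-equal and stratified and
their union is exactly the training set); bootstrap bags of size n are
available behind `bagging_mode="bootstrap"`. One base tree per bag. The
meta-table holds, per training row, the selected features followed by all
Z base predictions (so its width is n_selected + Z), and the
meta-classifier — the same gain-ratio tree family, keeping the ensemble
homogeneous — is trained on it. Because the meta-tree sees the raw
features too, its training error cannot exceed a majority vote's on
feature-separable rows. Base predictions in the meta-table are in-bag
optimistic for each tree's own rows; `oob_meta=True` replaces those
entries by the majority vote of the other trees, trimming that optimism.
A single-class bag degenerates to a leaf tree and is recorded, not
fatal.

## Evaluation

Confusion counts take label 1 ("lives") as the positive class. Accuracy,
precision, recall and F1 follow the standard formulas; 0/0 ratios are
defined as 0 and flagged. Metrics are computed per fold, averaged over
the k folds of a run, then reported as mean (population SD) over repeated
runs — defaults k = 10, 20 runs. A single master seed fans out through
named substreams (shuffle, folds, HHO, binarization, bags, synthesis), so
two invocations with the same seed are bit-identical while components
remain independently replayable.

## Synthetic data

The generator draws labels Bernoulli(prevalence) first, then features:
dichotomous ~ Bernoulli(schema mean), ordinal ~ rounded truncated
normal, ratio ~ truncated normal (rejection sampling, capped at 100
resampling passes, then clamping). Informative features receive
prevalence-weighted class-conditional shifts — +e·σ·(1−p) for the
positive class, −e·σ·p for the negative (log-odds analogue for
dichotomous) — so the class gap is e standard deviations while the
marginal mean stays at the schema target. Missingness is injected MCAR
at per-feature rates; labels are never masked.

What this emulates: the reference table's scales, ranges, first two
moments, missingness rates and class balance, plus a controllable signal
for recovery studies. What it does not: real between-feature
correlations (no copulas), informative missingness (the real table's 8
complete rows out of 165 are far more than MCAR predicts at these rates —
under independence the expected count is below 1 — so the real mechanism
is co-missing blocks), and truncation bias for features whose printed
range cuts deep into the normal (the heavy-tailed laboratory values);
marginal-mean checks therefore apply to mildly truncated features.
Passing the recovery tests shows the machinery works under clean MCAR
conditions, not that the pipeline attains any particular accuracy on the
real clinical data.

## Problem sizes in the checks

The acceptance-style studies run at sizes a laptop core handles in
minutes: HHO convergence on a 5-D quadratic (N = 20, T = 200, 10 seeds);
planted-signal recovery at n = 300, m = 30, 5 informative features at
effect 1.0 (10 seeds, ensemble fitness with 3 internal folds, N = 15,
T = 30); the
ensemble-versus-tree comparison at n = 300, m = 10 over 20 seeds; the
full-pipeline demonstration on a 165 × 49 HCC-like table with 3 runs of
10-fold CV. The package defaults (N = 30, T = 100, ensemble fitness with
10 internal folds, 20 evaluation runs) remain the recommended settings
for real studies.

## Known limitations

- Wrapper selection with a stochastic binarization means the same
  continuous position can map to different masks across evaluations; the
  returned best-ever mask is well-defined, but the continuous rabbit is
  not itself the answer.
- The pooled (default) leakage mode overstates generalization; use
  strict mode for honest estimates.
- The gain-ratio criterion is applied to all candidate splits (no
  average-gain pre-filter as in some C4.5 variants).
- No probability calibration, ROC/AUC, or significance testing between
  pipeline variants.
- Iterative imputation assumes approximately linear conditional means;
  with qualitative features it regresses on category codes as numbers,
  then rounds.
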