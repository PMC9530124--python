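# Methods

This note documents the models, statistics and numerical choices behind
`vitalsign`, and what the synthetic test bench does and does not show.

## Mortality models

All-cause mortality at a follow-up horizon is modelled as a binary
classification problem on a subjects × features table. The primary model
is a gradient-boosted tree ensemble (xgboost, binary logistic objective):
margin output is log-odds, probability is the sigmoid of the margin, and
missing values route through each split's learned default direction, so
no imputation is applied to the tree model. Hyperparameters are chosen
by grid search with stratified 5-fold cross-validated AUROC on the
training split, ties broken by grid order, and the winner refit on the
full training data; the tuning record (grid point, per-fold AUROCs) is
kept on the model. The shipped default grid (depth {3, 6}, learning rate
{0.1, 0.05}, trees {100, 500}, min child weight {1, 10}) is a deliberate
placeholder — every analysis in this repository passes an explicit grid,
usually the single point depth 3 / 100 trees / rate 0.1, which is ample
for the synthetic bench. Class reweighting is off by default and exposed
as `scale_pos_weight`.

The linear comparison model is L2-regularized logistic regression with
median imputation and standardization (linear models cannot take missing
values natively). It shares the predict/evaluate interfaces so the two
model classes can be compared head-to-head.

Splits are either random 80/20 (seeded permutation) or temporal: all
enrollment cycles ≤ cutoff train, later cycles validate. Performance is
AUROC (probability a random positive outscores a random negative, ties
one-half), with a percentile 95% interval from 1000 bootstrap resamples
of test subjects by default; degenerate one-class resamples record the
point estimate rather than a bogus value.

## Shapley attributions

Attributions are interventional Shapley values of the margin: the value
of a coalition S is the background-average of f with features in S fixed
at the subject's values. For trees this expectation is exact per
background row — along each root-to-leaf path every feature's constraint
is satisfied by the subject's value, the background value, both, or
neither, which reduces each leaf to the coalition game
v·1[U ⊆ S, V ∩ S = ∅] with the closed-form Shapley shares
v(u−1)!w!/(u+w)! (for U members) and −v·u!(w−1)!/(u+w)! (for V members).
Averaging over the background yields attributions satisfying additivity
identically: base + Σφ = f(x) with base the background-mean margin. The
kernel is a numba loop over (subject, background row, leaf); thresholds
compare in float32 to reproduce xgboost's traversal bit-exactly, and the
base value is computed through the same float64 leaf-sum path as φ so
the additivity error is pure float64 accumulation (~1e-12 relative).

The background defaults to a 64-row seeded sub-sample of the explained
(or training) table — the estimator is unbiased in the background
sample, and 64 rows keep the cost linear and small; analyses that need
tighter Monte-Carlo error can raise `max_background`.

Pairwise interaction values use the condition-in/condition-out
construction: Φ_ij = ½(φ_j with i forced present − φ_j with i forced
absent), computed with the same kernel (forcing adjusts the per-leaf
game), symmetrized, with main effects Φ_ii = φ_i − Σ_{j≠i} Φ_ij so each
row sums to φ_i. A brute-force enumeration oracle over all 2^d
coalitions (capped at 12 features) validates both attributions and
interactions on small random ensembles; it is the correctness standard,
never the production path.

Explanations of *risk scores* are presented in probability space:
log-odds attributions are rescaled by (risk − base risk)/Σφ so the base
value (mean predicted risk) plus contributions reconstructs the
subject's risk exactly. This proportional conversion is an
approximation — it preserves sign and relative magnitude but not the
Shapley axioms in probability space; the zero-sum case maps to zero
contributions.

## Supervised distance and selection

The redundancy metric between features i and j with respect to a label:
fit a univariate GBT of the label from i (library-default
hyperparameters, probability-space output by default; margin space is
available), giving P_i; fit a univariate squared-error GBT of P_i from
j, giving P_i^j; then R²(i,j) = max(0, 1 − mean((P_i − P_i^j)²/var(P_i)))
and distance = max(1 − R²(i,j), 1 − R²(j,i)). All fits and predictions
use the training split only. A constant univariate prediction
(var(P_i) = 0) defines R² = 0 — a feature carrying no label information
is not redundant with anything. The all-pairs matrix caches each P_i and
reuses it for every pair, which is exactly equivalent to naive
recomputation. Redundant groups come from complete-linkage hierarchical
clustering (scipy) of the matrix.

Selection iterates: fit the full model, rank by mean |φ|, cluster the
non-anchor features (anchors: age and sex, always retained) into
(current − 5) groups, keep each cluster's most important member, refit,
and record the feature set, held-out bootstrap AUROC and minimum
pairwise supervised distance; iteration stops when the non-anchor
features form a single cluster. Clustering is re-run on each surviving
set, but pair distances are cached across iterations (they depend only
on the pair and the label). Hyperparameters are not re-tuned per
iteration (cost; exposed via the `grid` argument).

## Relative risk curves and the RRP audit

The relative-risk curve of a feature substitutes each grid value into
every test subject, averages the predicted probability and divides by
the unmodified mean prediction, so r = 1 is cohort-average risk. The
default grid is 100 points at empirical percentiles 0.5–99.5
(tail-robust); the interval audit additionally injects 11 points
spanning each audited interval so intervals in sparse tails are always
sampled. An interval scores RRP = 100·(max_{RI} r − 1)/(max r − 1): 100%
iff it contains the global risk maximum, negative if risk inside stays
below average, 0 by convention for a flat curve (excess risk < 1e-6).
The maximum (rather than mean or boundary) statistic inside the interval
was chosen because it is the only variant that saturates exactly at 100%
for an interval covering the riskiest values, matching the audit's
intent of flagging "normal ranges" that contain high-risk values; the
formula is a reconstruction and is documented as such. Intervals with
RRP above 50% are flagged sub-optimal by default (configurable). Because
RRP is a ratio of relative risks it is invariant to rescaling all
predictions by a positive constant. Sex-specific intervals are evaluated
on the matching stratum (sex coded 1 = male, 0 = female).

## Risk scores

A risk score is the predicted event probability of a model trained on a
tier-restricted pool: `public` (demographic + examination +
questionnaire — collectable at home), `professional` (demographic +
laboratory), `panel` (demographic + an explicit named lab panel; the
shipped default panel is a placeholder over synthetic labs), or `all`.
Within the pool, recursive feature elimination drops the 5 least
important features (mean |φ|) per refit until the requested size.
Evaluations attach overall and per-sex bootstrap AUROCs; temporal
validation scores the model on subjects from enrollment cycles strictly
later than every training cycle and rejects any overlap.

## The synthetic cohort

The generator emulates the shape of a national health-survey cohort
while planting known structure. Marginals: age ~ U(18, 85), sex ~
Bernoulli(0.5), continuous labs Gaussian or log-normal. The mortality
mechanism is logistic: logit p = β0(h) + Σ w_e g_e(x) with effect shapes

- monotone: g = z (standardized value);
- U-shape(v0, c): g = c·((x − v0)/sd)², zero and risk-minimal at v0;
- threshold(knot): g = (min(x, knot) − knot)/sd — rising below the
  knot, exactly flat above it;
- interaction: g = z(x)·z(partner), multiplicative on log-odds.

β0 defaults to logit(0.08) at the 5-year horizon with a log(h/5) shift
per horizon; labels are nested across horizons through a single latent
uniform per subject (each horizon's label is marginally Bernoulli(p_h)
and shorter-horizon deaths are contained in longer ones). The default
cohort (8,000 subjects, ~20 features plus noise labs; missingness 5%
MCAR on non-demographic features) carries a dominant age effect, a
protective body-size signal observed through four redundant
anthropometric proxies of one latent (member noise 5–8% of scale), a
U-shaped urate-like lab (optimum 5.0, right of which the longer tail
makes the upper extreme the unambiguous risk maximum), a saturating
urine-albumin-like lab (knot 150 in a log-normal tail), monotone RDW-
and lead-like labs, an age×lead interaction (younger subjects hurt more
by lead) and a sex×chloride interaction, two questionnaire signals, and
pure-noise labs.

Reference-interval metadata comes from the *true* risk curve: the
"optimal" interval is the contiguous low-risk (r ≤ 1) run containing the
risk minimum; the deliberately "mis-set" interval covers the top-risk
plateau (the contiguous region with excess relative risk above half its
maximum), padded and extended past the sampling range at open ends so
the maximal-risk values always fall inside. Flat-curve and binary
features have no meaningful interval and are rejected.

What the bench does not emulate: survey weights and cycle design, real
marginal distributions or their correlations beyond the planted block,
informative missingness (MCAR only), censoring, and covariate drift
across cycles. Passing tests therefore demonstrate that the machinery
recovers structure it is able to represent, not that it would rank real
risk factors identically.

## Numerical and scale choices

- Ties in importance rankings break lexicographically on feature name;
  clustering and selection are deterministic given seeds.
- One root seed fans out to per-stage seeds via
  `numpy.random.SeedSequence.spawn` in the pipeline and acceptance
  script.
- Test and acceptance runs use the default cohort at 8,000 subjects,
  single-point grids, 64-row attribution backgrounds, 250–300-subject
  foregrounds for interaction tensors, and 50–1000 bootstrap replicates
  depending on context — sizes chosen so each planted property is
  comfortably detectable while keeping full runs in minutes.
- Recovery properties are asserted by majority vote over 5 cohort seeds,
  matching the stochastic nature of fitted-model artifacts.
- The U-shape optimum is estimated as the vertex of a least-squares
  parabola fit to the per-subject main effects over the central 98% of
  feature values — far more stable than the argmin of binned means when
  the true minimum region is flat.

## Known limitations

- Interventional Tree SHAP cost grows as subjects × background × total
  leaf-path length; interaction tensors multiply that by 2·d. Use
  foreground/background subsampling for large cohorts.
- The probability-space explanation rescaling is heuristic (see above).
- The RRP formula is a reconstruction pinned down by its qualitative
  contract (sign, 100% saturation, rescaling invariance).
- Univariate supervised-distance fits use library-default GBT
  hyperparameters by definition; with very small samples the distance of
  weakly informative pairs is noisy.
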