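# vitalsign

Explainable all-cause mortality risk modelling on tabular survey cohorts:
gradient-boosted trees plus exact Shapley-value explanations, with the
bespoke statistics that turn those explanations into epidemiological
tools — a *supervised distance* for feature redundancy, a
*relative risk percentage* (RRP) audit of laboratory reference intervals,
and tiered, cost-aware mortality risk scores built by SHAP-importance
recursive feature elimination.

The package is aimed at biostatisticians and epidemiologists who want
the accuracy of tree ensembles on cohort tables (demographics,
examination, laboratory and questionnaire features, with missing values)
without giving up interpretability. Because real survey data cannot ship
with a package, a first-class synthetic cohort generator plants known
structure — U-shaped, saturating-threshold and monotone risk effects,
age×exposure and sex×lab interactions, a redundant anthropometric block,
pure-noise labs, and per-feature reference-interval metadata — so every
downstream claim is testable against ground truth.

## The statistics at the core

**Attributions.** For a tree ensemble with margin (log-odds) output
f(x), each subject's prediction is decomposed into per-feature Shapley
values φ_j under the interventional convention (coalition expectations
estimated by averaging over a background sample), satisfying exactly

    f(x) = base + Σ_j φ_j,   base = E_background[f]

with pairwise interaction values Φ_ij (diagonal = main effects) whose
row sums reproduce φ. A brute-force coalition-enumeration oracle (≤ 12
features) validates both.

**Supervised distance.** For features i, j and a prediction task, let
P_i be the output of a univariate gradient-boosted model of the label
from feature i, and P_i^j the output of a univariate model of P_i from
feature j. Then

    supervised R²(i,j) = max(0, 1 − mean((P_i − P_i^j)² / var(P_i)))
    supervised distance(i,j) = max(1 − R²(i,j), 1 − R²(j,i))

Distance ≈ 0 means the features are redundant *for this task*; ≈ 1 means
not redundant. Complete-linkage clustering of the distance matrix finds
redundant groups; recursive selection keeps each cluster's most
important member (by mean |φ|), trading redundancy against accuracy.

**RRP.** With the relative-risk curve r(v) (mean predicted probability
with the feature fixed at v, normalized by the cohort mean prediction),
an interval [lo, hi] scores

    RRP = 100 × (max_{v∈[lo,hi]} r(v) − 1) / (max_v r(v) − 1)

RRP = 100% iff the interval contains the global risk maximum (a "normal
range" covering the riskiest values); negative RRP means risk inside the
interval stays below the cohort average.

## Worked example

```python
import vitalsign as vs

spec = vs.default_cohort_spec(n_subjects=8000, seed=7)
table, labels, truth = vs.generate_cohort(spec)
y = labels["death_5y"].to_numpy()
train, test = vs.split_cohort(table, "random_80_20", seed=7)

model = vs.fit_gbt(table.subset_rows(train), y[train],
                   grid={"max_depth": [3], "n_estimators": [100]}, seed=7)
ev = vs.evaluate_auroc(vs.predict_risk(model, table.subset_rows(test)),
                       y[test], n_boot=1000, seed=7)
print(round(ev.auroc, 3), [round(ev.ci_low, 3), round(ev.ci_high, 3)])

rank = vs.importance(vs.attribute(model, table.subset_rows(train), seed=7))
print(rank.features[:5])
```

prints

```
0.79 [0.747, 0.829]
['age', 'rdw', 'urine_albumin', 'serum_chloride', 'blood_lead']
```

— the held-out 5-year AUROC with its 95% bootstrap interval, and the
five globally most important features (all planted signals: the
dominant age effect, the monotone red-cell-distribution-width-like lab,
the saturating urine-albumin-like lab, and the interaction-carrying
chloride and lead exposures), recovered ahead of every pure-noise
feature.

The full analysis lives in `analysis/01_simulate.py` …
`analysis/06_risk_scores.py` — numbered drivers that generate the
cohort, train and compare models, explain them, map redundancy, audit
reference intervals, and build tiered risk scores, writing tables under
`results/`.

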