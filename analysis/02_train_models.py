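"""Train the 5-year mortality models and compare the tree ensemble with
the logistic baseline across follow-up horizons.

The tree model sees missing values natively; the logistic baseline gets
median imputation.  Both are evaluated with 1000-replicate bootstrap
AUROC on the held-out 20%.  Writes results/model_auroc.csv.
"""

from pathlib import Path

import pandas as pd

import vitalsign as vs

from _common import OUT, SEED, get_cohort

GRID = {"max_depth": [3, 4], "n_estimators": [100], "learning_rate": [0.1]}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table, labels = get_cohort()
    train_idx, test_idx = vs.split_cohort(table, "random_80_20", seed=SEED)
    train, test = table.subset_rows(train_idx), table.subset_rows(test_idx)

    rows = []
    for col in labels.columns:
        y = labels[col].to_numpy()
        gbt = vs.fit_gbt(train, y[train_idx], grid=GRID, seed=SEED)
        lin = vs.fit_linear_baseline(train, y[train_idx], seed=SEED)
        for name, model in (("gbt", gbt), ("logistic", lin)):
            ev = vs.evaluate_auroc(
                vs.predict_risk(model, test), y[test_idx], n_boot=1000, seed=SEED
            )
            rows.append(
                {"horizon": col, "model": name, "auroc": ev.auroc,
                 "ci_low": ev.ci_low, "ci_high": ev.ci_high}
            )
            print(f"{col:10s} {name:9s} AUROC {ev.auroc:.4f} "
                  f"[{ev.ci_low:.4f}, {ev.ci_high:.4f}]")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "model_auroc.csv", index=False)
    gap = (df[df.model == "gbt"].auroc.values
           - df[df.model == "logistic"].auroc.values)
    print(f"mean GBT - logistic AUROC gap across horizons: {gap.mean():+.4f}")
    print("(the default cohort is dominated by monotone effects, so the "
          "linear baseline is competitive there)")

    # where the tree model earns its keep: U-shape + interaction structure
    spec = vs.CohortSpec(
        n_subjects=4000,
        features=(
            vs.FeatureDef("age", "demographic", ("uniform", 18.0, 85.0)),
            vs.FeatureDef("lab_u", "laboratory", ("normal", 5.5, 1.5)),
            vs.FeatureDef("exposure", "laboratory", ("normal", 0.0, 1.0)),
        ),
        effects=(
            vs.PlantedEffect("lab_u", vs.UShape(optimum=5.5, curvature=0.8), 1.2),
            vs.PlantedEffect("exposure", vs.Interaction(partner="age"), 1.0),
        ),
        n_noise_features=2, missing_rate=0.0, beta0=-1.5, seed=SEED,
    )
    ntab, nlab, _ = vs.generate_cohort(spec)
    ny = nlab["death_5y"].to_numpy()
    ntr, nte = vs.split_cohort(ntab, seed=SEED)
    ngbt = vs.fit_gbt(ntab.subset_rows(ntr), ny[ntr], grid=GRID, seed=SEED)
    nlin = vs.fit_linear_baseline(ntab.subset_rows(ntr), ny[ntr], seed=SEED)
    a_g = vs.auroc(vs.predict_risk(ngbt, ntab.subset_rows(nte)), ny[nte])
    a_l = vs.auroc(vs.predict_risk(nlin, ntab.subset_rows(nte)), ny[nte])
    pd.DataFrame(
        [{"model": "gbt", "auroc": a_g}, {"model": "logistic", "auroc": a_l}]
    ).to_csv(OUT / "model_auroc_nonlinear.csv", index=False)
    print(f"pure U-shape + interaction cohort: GBT {a_g:.4f} vs "
          f"logistic {a_l:.4f} (gap {a_g - a_l:+.4f}) — nonlinear and "
          "interaction structure is invisible to the untransformed linear model")


if __name__ == "__main__":
    main()
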