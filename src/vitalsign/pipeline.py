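"""End-to-end pipeline: simulate -> train -> explain -> redundancy ->
reference-interval audit -> risk scores, with a reproducibility manifest.

One root seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn``, so every stage (simulation, CV,
bootstrap, background sub-sampling) is independently and reproducibly
seeded.  All tabular artifacts are plain delimited text; the manifest
records sizes, seeds and content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import cohort as cohort_mod
from .containers import FeatureTable
from .io import write_cohort
from .models import evaluate_auroc, fit_gbt, fit_linear_baseline, predict_risk, split_cohort
from .redundancy import distance_matrix, cluster_features, sd_feature_selection
from .reference_range import ReferenceInterval, audit_intervals
from .risk_score import FeatureTier, build_risk_score, explain_individual, waterfall_text
from .shapley import attribute, importance

log = logging.getLogger("vitalsign")


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    n_subjects: int = Field(5000, gt=0)
    label: str = "death_5y"
    horizons: list[int] = [5]
    test_size: float = Field(0.2, gt=0.0, lt=1.0)
    grid: dict[str, list] = {"max_depth": [3], "n_estimators": [100]}
    n_boot: int = Field(200, gt=0)
    risk_score_size: int = Field(8, gt=0)
    tiers: list[str] = ["public", "professional", "all"]
    run_selection: bool = True

    @model_validator(mode="after")
    def _check(self):
        if not self.label.startswith("death_"):
            raise ValueError("label must be a death_<h>y column")
        if int(self.label.removeprefix("death_").removesuffix("y")) not in self.horizons:
            raise ValueError("label horizon missing from horizons")
        return self


def _stage_seeds(root: int, names: list[str]) -> dict[str, int]:
    seqs = np.random.SeedSequence(root).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, seqs)}


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Any stage failure raises with the stage name; artifacts written by
    earlier stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    seeds = _stage_seeds(
        config.seed,
        ["simulate", "split", "train", "attribute", "redundancy", "rrp", "riskscore"],
    )
    manifest: dict = {"seeds": seeds, "stages": {}, "hashes": {}}
    stage = "simulate"
    try:
        spec = cohort_mod.default_cohort_spec(
            n_subjects=config.n_subjects, seed=seeds["simulate"]
        )
        spec.horizons = tuple(config.horizons)
        table, labels, truth = cohort_mod.generate_cohort(spec)
        write_cohort(out / "cohort.csv", table, labels)
        y = labels[config.label].to_numpy()
        manifest["stages"][stage] = {"n": table.n_subjects, "features": len(table.features)}

        stage = "split"
        train_idx, test_idx = split_cohort(table, "random_80_20", seed=seeds["split"])
        manifest["stages"][stage] = {"train": len(train_idx), "test": len(test_idx)}

        stage = "train"
        train_tab = table.subset_rows(train_idx)
        test_tab = table.subset_rows(test_idx)
        gbt = fit_gbt(train_tab, y[train_idx], grid=config.grid, seed=seeds["train"])
        lin = fit_linear_baseline(train_tab, y[train_idx], seed=seeds["train"])
        ev_gbt = evaluate_auroc(
            predict_risk(gbt, test_tab), y[test_idx], config.n_boot, seeds["train"]
        )
        ev_lin = evaluate_auroc(
            predict_risk(lin, test_tab), y[test_idx], config.n_boot, seeds["train"]
        )
        pd.DataFrame(
            [
                {"model": "gbt", "auroc": ev_gbt.auroc, "ci_low": ev_gbt.ci_low,
                 "ci_high": ev_gbt.ci_high},
                {"model": "logistic", "auroc": ev_lin.auroc, "ci_low": ev_lin.ci_low,
                 "ci_high": ev_lin.ci_high},
            ]
        ).to_csv(out / "model_comparison.csv", index=False)
        manifest["stages"][stage] = {"gbt_auroc": ev_gbt.auroc, "logistic_auroc": ev_lin.auroc}

        stage = "attribute"
        attr = attribute(gbt, test_tab, background=train_tab, seed=seeds["attribute"])
        rank = importance(attr)
        attr.phi.to_csv(out / "attributions.csv", index=False, na_rep="NA")
        pd.DataFrame({"feature": rank.features, "mean_abs_phi": rank.values}).to_csv(
            out / "importance.csv", index=False
        )
        manifest["stages"][stage] = {"base_value": attr.base_value, "top": rank.features[:5]}

        stage = "redundancy"
        dm = distance_matrix(table, y, train_idx, seed=seeds["redundancy"])
        dm.as_frame().to_csv(out / "supervised_distance.csv")
        clust = cluster_features(dm, k=max(2, len(table.features) - 12))
        pd.DataFrame(
            {"feature": dm.features, "cluster": [clust.assignment[f] for f in dm.features]}
        ).to_csv(out / "feature_clusters.csv", index=False)
        np.savetxt(
            out / "linkage.txt", clust.linkage_matrix,
            header="id1 id2 height size", comments="#",
        )
        if config.run_selection:
            traj = sd_feature_selection(
                table, y, train_idx, test_idx, grid=config.grid,
                n_boot=config.n_boot, seed=seeds["redundancy"],
            )
            pd.DataFrame(
                [
                    {"size": len(r.features), "auroc": r.evaluation.auroc,
                     "min_supervised_distance": r.min_supervised_distance,
                     "features": "|".join(r.features)}
                    for r in traj
                ]
            ).to_csv(out / "selection_trajectory.csv", index=False)
        manifest["stages"][stage] = {"n_pairs": len(dm.features) ** 2}

        stage = "rrp"
        intervals = []
        for feat, ris in truth.reference_intervals.items():
            intervals.append(ReferenceInterval(feat, *ris["optimal"]))
            intervals.append(ReferenceInterval(feat, *ris["mis_set"]))
        tag = config.label.removeprefix("death_")
        audit = audit_intervals({tag: gbt}, test_tab, intervals, n_grid=50)
        audit.to_csv(out / "rrp_audit.csv", index=False)
        manifest["stages"][stage] = {"n_intervals": len(intervals)}

        stage = "riskscore"
        scores = {}
        for tier_name in config.tiers:
            score = build_risk_score(
                table, y, train_idx, test_idx, FeatureTier(tier_name),
                size=config.risk_score_size, grid=config.grid,
                n_boot=config.n_boot, seed=seeds["riskscore"],
            )
            scores[tier_name] = score
        pd.DataFrame(
            [
                {"tier": t, "size": len(s.features),
                 "auroc": s.evaluations["overall"].auroc,
                 "features": "|".join(s.features)}
                for t, s in scores.items()
            ]
        ).to_csv(out / "risk_scores.csv", index=False)
        expl = explain_individual(
            scores[config.tiers[0]], test_tab.data.iloc[0], seed=seeds["riskscore"]
        )
        (out / "example_explanation.txt").write_text(waterfall_text(expl))
        manifest["stages"][stage] = {t: s.evaluations["overall"].auroc for t, s in scores.items()}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    for p in sorted(out.glob("*.csv")):
        manifest["hashes"][p.name] = _sha(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
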