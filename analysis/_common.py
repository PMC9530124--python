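"""Shared analysis configuration: one deterministic study cohort.

The cohort file is large, so it is not kept under version control;
``get_cohort`` loads it if `01_simulate.py` has been run and otherwise
regenerates it in memory (same spec, same seed — byte-identical).
"""

from pathlib import Path

import vitalsign as vs

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7
GRID = {"max_depth": [3], "n_estimators": [100], "learning_rate": [0.1]}


def get_cohort():
    path = OUT / "cohort.csv"
    if path.exists():
        table, labels = vs.read_cohort(path)
        return table, labels
    spec = vs.default_cohort_spec(n_subjects=8000, seed=SEED)
    table, labels, _ = vs.generate_cohort(spec)
    return table, labels
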