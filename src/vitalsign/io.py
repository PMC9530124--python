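"""Cohort readers/writers: delimited text + JSON sidecar for metadata.

A cohort on disk is a CSV with a header row, ``NA`` (or empty) for
missing entries, optional label columns (``death_*``) and an optional
``cycle`` column, plus a ``<stem>.meta.json`` sidecar carrying feature
roles and any generator metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable

log = logging.getLogger("vitalsign")

NA_TOKENS = ["NA", ""]
RESERVED = ("cycle",)


def write_cohort(
    path: str | Path,
    table: FeatureTable,
    labels: pd.DataFrame | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write table (+ labels, cycle) as CSV with an ``NA`` missing token
    and the roles in a JSON sidecar."""
    path = Path(path)
    df = table.data.copy()
    if labels is not None:
        for c in labels.columns:
            df[c] = labels[c].to_numpy()
    if table.cycle is not None:
        df["cycle"] = table.cycle
    df.to_csv(path, index=False, na_rep="NA")
    meta = {"roles": dict(table.roles)}
    if extra_meta:
        meta.update(extra_meta)
    sidecar = path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=_jsonable))
    return path


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_cohort(
    path: str | Path,
    roles: dict[str, str] | None = None,
    label_prefix: str = "death_",
) -> tuple[FeatureTable, pd.DataFrame]:
    """Read a cohort CSV back into a FeatureTable plus label columns.

    Missing tokens (``NA`` or empty) become NaN; roles come from the
    sidecar unless given explicitly.  Duplicate columns and non-numeric
    values are rejected with the offending column (and line numbers for
    values).
    """
    path = Path(path)
    raw_first = path.open().readline().rstrip("\n").split(",")
    dupes = sorted({c for c in raw_first if raw_first.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicate feature names in {path.name}: {dupes}")
    df = pd.read_csv(path, na_values=NA_TOKENS, keep_default_na=False)
    for c in df.columns:
        if df[c].dtype == object:
            numeric = pd.to_numeric(df[c], errors="coerce")
            bad = df.index[numeric.isna() & df[c].notna()]
            if len(bad):
                lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-basing
                raise ValueError(
                    f"non-numeric values in column {c!r} at lines {lines}"
                )
            df[c] = numeric
    label_cols = [c for c in df.columns if c.startswith(label_prefix)]
    labels = df[label_cols].astype(int) if label_cols else pd.DataFrame(index=df.index)
    cycle = df["cycle"].to_numpy() if "cycle" in df.columns else None
    feats = [c for c in df.columns if c not in label_cols and c not in RESERVED]
    if roles is None:
        sidecar = path.with_name(path.stem + ".meta.json")
        if sidecar.exists():
            roles = json.loads(sidecar.read_text())["roles"]
        else:
            roles = {c: "laboratory" for c in feats}
    table = FeatureTable(df[feats], {c: roles[c] for c in feats}, cycle=cycle)
    miss = table.missingness()
    log.info(
        "read %s: %d subjects, %d features, mean missingness %.3f",
        path.name, table.n_subjects, len(feats), float(miss.mean()),
    )
    return table, labels
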