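"""Parse an xgboost binary-logistic booster into flat leaf/path arrays.

For every leaf we record its value and, for every distinct feature on its
root-to-leaf path, the list of split conditions the sample must satisfy to
reach the leaf.  A sample "satisfies" a path feature iff it routes to the
path's side at every split on that feature (NaN follows the recorded
missing direction).  Comparisons are done in float32, matching xgboost's
internal traversal exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass
class TreeLeaves:
    leaf_value: np.ndarray  # float64[n_leaves]
    slot_ptr: np.ndarray  # int32[n_leaves + 1]; slots of leaf l
    slot_feat: np.ndarray  # int32[n_slots]; feature index of each slot
    cond_ptr: np.ndarray  # int32[n_slots + 1]; conditions of slot s
    cond_thr: np.ndarray  # float32[n_conds]
    cond_left: np.ndarray  # uint8[n_conds]; 1 if the path goes left here
    cond_missing_left: np.ndarray  # uint8[n_conds]; 1 if NaN routes left


@dataclass
class ParsedEnsemble:
    trees: list[TreeLeaves]
    base_margin: float  # logit of the learner's base_score
    n_features: int
    max_path_features: int


def parse_booster(booster, n_features: int) -> ParsedEnsemble:
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    base_margin = float(np.log(base_score / (1.0 - base_score)))
    trees = []
    max_path = 1
    for dump in booster.get_dump(dump_format="json"):
        tree = json.loads(dump)
        leaves: list[tuple[float, dict]] = []

        def walk(node, path):
            if "leaf" in node:
                leaves.append((float(node["leaf"]), {f: list(cs) for f, cs in path.items()}))
                return
            f = int(node["split"][1:])
            thr = np.float32(node["split_condition"])
            kids = {c["nodeid"]: c for c in node["children"]}
            miss_left = node["missing"] == node["yes"]
            for go_left, child_id in ((True, node["yes"]), (False, node["no"])):
                path.setdefault(f, [])
                path[f].append((thr, go_left, miss_left))
                walk(kids[child_id], path)
                path[f].pop()
                if not path[f]:
                    del path[f]

        walk(tree, {})

        leaf_value, slot_ptr, slot_feat = [], [0], []
        cond_ptr, cond_thr, cond_left, cond_missing = [0], [], [], []
        for val, path in leaves:
            leaf_value.append(val)
            max_path = max(max_path, len(path))
            for f in sorted(path):
                slot_feat.append(f)
                for thr, go_left, miss_left in path[f]:
                    cond_thr.append(thr)
                    cond_left.append(1 if go_left else 0)
                    cond_missing.append(1 if miss_left else 0)
                cond_ptr.append(len(cond_thr))
            slot_ptr.append(len(slot_feat))
        trees.append(
            TreeLeaves(
                np.asarray(leaf_value, dtype=np.float64),
                np.asarray(slot_ptr, dtype=np.int32),
                np.asarray(slot_feat, dtype=np.int32),
                np.asarray(cond_ptr, dtype=np.int32),
                np.asarray(cond_thr, dtype=np.float32),
                np.asarray(cond_left, dtype=np.uint8),
                np.asarray(cond_missing, dtype=np.uint8),
            )
        )
    return ParsedEnsemble(trees, base_margin, n_features, max_path)


def slot_satisfaction(tree: TreeLeaves, X: np.ndarray) -> np.ndarray:
    """Boolean matrix [n_samples, n_slots]: does the sample satisfy every
    split condition of the slot's feature along the leaf's path?"""
    X32 = np.asarray(X, dtype=np.float32)
    n = X32.shape[0]
    ns = len(tree.slot_feat)
    sat = np.ones((n, ns), dtype=np.bool_)
    for s in range(ns):
        f = tree.slot_feat[s]
        col = X32[:, f]
        isnan = np.isnan(col)
        for c in range(tree.cond_ptr[s], tree.cond_ptr[s + 1]):
            goes_left = np.where(
                isnan, bool(tree.cond_missing_left[c]), col < tree.cond_thr[c]
            )
            sat[:, s] &= goes_left == bool(tree.cond_left[c])
    return sat


def margin_from_leaves(ens: ParsedEnsemble, X: np.ndarray) -> np.ndarray:
    """Model margin recomputed from the parsed trees (verification path)."""
    out = np.full(X.shape[0], ens.base_margin, dtype=np.float64)
    for tree in ens.trees:
        sat = slot_satisfaction(tree, X)
        for l in range(len(tree.leaf_value)):
            sl = slice(tree.slot_ptr[l], tree.slot_ptr[l + 1])
            reach = sat[:, sl].all(axis=1)
            out[reach] += tree.leaf_value[l]
    return out
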