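"""Shapley-value attributions for tree-ensemble mortality models.

Attributions use the interventional convention: the conditional expectation
of the model under a coalition is estimated by averaging over a background
sample with out-of-coalition features replaced by background values.  For a
tree ensemble this expectation is exact per background row: each leaf
contributes through the closed form for the induced coalition game

    g(S) = leaf_value * 1[U subset of S, V disjoint from S]

where U (resp. V) are the path features satisfied only by the explained
sample (resp. only by the background row).  The Shapley value of a U member
is ``v (u-1)! w! / (u+w)!`` and of a V member ``-v u! (w-1)! / (u+w)!``;
all other features are null players.  Averaging over the background yields
attributions that satisfy additivity exactly:

    base + sum_j phi_j = margin(x),  base = mean margin over background.

Pairwise interaction values use the standard condition-in/condition-out
construction (half the difference of the partner's Shapley value with the
feature forced present vs forced absent), with main effects on the
diagonal so every row sums back to the feature's phi.

``brute_force_shapley`` is the independent enumeration oracle (<= 12
features) used to validate all of the above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import fisher_exact, spearmanr

from ._trees import ParsedEnsemble, margin_from_leaves, parse_booster, slot_satisfaction
from .containers import FeatureTable
from .models import TrainedModel, _matrix


@dataclass
class AttributionSet:
    """Per-subject additive attributions in margin (log-odds) space."""

    phi: pd.DataFrame  # subjects x features
    base_value: float
    model_tag: str = "gbt"

    @property
    def features(self) -> list[str]:
        return list(self.phi.columns)


@dataclass
class InteractionTensor:
    """Per-subject symmetric feature x feature interaction decomposition."""

    values: np.ndarray  # [n_subjects, d, d]
    features: list[str]
    base_value: float

    def phi(self) -> np.ndarray:
        """Row sums: recover the per-subject attribution vector."""
        return self.values.sum(axis=2)

    def main_effects(self) -> pd.DataFrame:
        d = np.arange(len(self.features))
        return pd.DataFrame(self.values[:, d, d], columns=self.features)


@dataclass
class ImportanceRanking:
    """Features ordered by descending mean |phi|, ties lexicographic."""

    features: list[str]
    values: np.ndarray
    model_tag: str = "gbt"

    def rank_of(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.features)}


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _accumulate_tree(satx, satb, slot_feat, slot_ptr, leaf_val, forced, wpos, wneg, phi):
    nx = satx.shape[0]
    nb = satb.shape[0]
    nl = leaf_val.shape[0]
    for i in range(nx):
        for j in range(nb):
            for l in range(nl):
                u = 0
                w = 0
                dead = False
                for s in range(slot_ptr[l], slot_ptr[l + 1]):
                    f = slot_feat[s]
                    sx = satx[i, s]
                    sb = satb[j, s]
                    fc = forced[f]
                    if fc == 1:
                        if not sx:
                            dead = True
                            break
                    elif fc == 0:
                        if not sb:
                            dead = True
                            break
                    else:
                        if sx:
                            if not sb:
                                u += 1
                        elif sb:
                            w += 1
                        else:
                            dead = True
                            break
                if dead or (u == 0 and w == 0):
                    continue
                v = leaf_val[l]
                pu = v * wpos[u, w]
                pv = -v * wneg[u, w]
                for s in range(slot_ptr[l], slot_ptr[l + 1]):
                    f = slot_feat[s]
                    if forced[f] != -1:
                        continue
                    sx = satx[i, s]
                    sb = satb[j, s]
                    if sx and not sb:
                        phi[i, f] += pu
                    elif sb and not sx:
                        phi[i, f] += pv


def _shapley_weight_tables(max_players: int) -> tuple[np.ndarray, np.ndarray]:
    m = max_players + 1
    wpos = np.zeros((m, m))
    wneg = np.zeros((m, m))
    for u in range(m):
        for w in range(m - u):
            if u >= 1:
                wpos[u, w] = math.exp(
                    math.lgamma(u) + math.lgamma(w + 1) - math.lgamma(u + w + 1)
                )
            if w >= 1:
                wneg[u, w] = math.exp(
                    math.lgamma(u + 1) + math.lgamma(w) - math.lgamma(u + w + 1)
                )
    return wpos, wneg


def _ensemble_phi(
    ens: ParsedEnsemble,
    X: np.ndarray,
    background: np.ndarray,
    forced: np.ndarray | None = None,
) -> np.ndarray:
    d = ens.n_features
    if forced is None:
        forced = np.full(d, -1, dtype=np.int8)
    wpos, wneg = _shapley_weight_tables(ens.max_path_features)
    phi = np.zeros((X.shape[0], d))
    for tree in ens.trees:
        satx = slot_satisfaction(tree, X)
        satb = slot_satisfaction(tree, background)
        _accumulate_tree(
            satx,
            satb,
            tree.slot_feat,
            tree.slot_ptr,
            tree.leaf_value,
            forced,
            wpos,
            wneg,
            phi,
        )
    phi /= background.shape[0]
    return phi


# ---------------------------------------------------------------------------
# public operations


def _resolve_background(
    model: TrainedModel,
    table: FeatureTable | pd.DataFrame,
    background,
    max_background: int,
    seed: int,
) -> np.ndarray:
    if background is None:
        bg = getattr(model, "background", None)
        if bg is None:
            bg = _matrix(table, model.features)
    elif isinstance(background, (FeatureTable, pd.DataFrame)):
        bg = _matrix(background, model.features)
    else:
        bg = np.asarray(background, dtype=np.float64)
    if bg.shape[0] > max_background:
        rng = np.random.default_rng(seed)
        bg = bg[rng.choice(bg.shape[0], size=max_background, replace=False)]
    return bg


def attribute(
    model: TrainedModel,
    table: FeatureTable | pd.DataFrame,
    background: FeatureTable | pd.DataFrame | np.ndarray | None = None,
    max_background: int = 64,
    seed: int = 0,
) -> AttributionSet:
    """Interventional Shapley attributions for every subject in ``table``.

    ``background`` defaults to the explained table itself (or the rows
    attached to the model at fit time, if present), sub-sampled to
    ``max_background`` rows for tractability.  Additivity holds exactly:
    ``base_value + phi.sum(1) == margin``.
    """
    if model.kind != "gbt":
        raise ValueError("attributions are defined for the tree model only")
    X = _matrix(table, model.features)
    bg = _resolve_background(model, table, background, max_background, seed)
    ens = parse_booster(model.model.get_booster(), len(model.features))
    phi = _ensemble_phi(ens, X, bg)
    # base through the same float64 leaf-sum path as phi, so that
    # base + sum(phi) reproduces the margin to float64 accumulation error
    base = float(np.mean(margin_from_leaves(ens, bg)))
    index = table.data.index if isinstance(table, FeatureTable) else table.index
    return AttributionSet(pd.DataFrame(phi, columns=model.features, index=index), base)


def interactions(
    model: TrainedModel,
    table: FeatureTable | pd.DataFrame,
    background: FeatureTable | pd.DataFrame | np.ndarray | None = None,
    max_background: int = 64,
    seed: int = 0,
) -> InteractionTensor:
    """Pairwise Shapley interaction values; diagonal = main effects.

    Symmetric in (i, j); each subject's row sums reproduce the phi vector
    of :func:`attribute` with the same background.
    """
    if model.kind != "gbt":
        raise ValueError("interactions are defined for the tree model only")
    X = _matrix(table, model.features)
    bg = _resolve_background(model, table, background, max_background, seed)
    ens = parse_booster(model.model.get_booster(), len(model.features))
    d = len(model.features)
    n = X.shape[0]
    phi = _ensemble_phi(ens, X, bg)
    tensor = np.zeros((n, d, d))
    for i in range(d):
        forced = np.full(d, -1, dtype=np.int8)
        forced[i] = 1
        plus = _ensemble_phi(ens, X, bg, forced)
        forced[i] = 0
        minus = _ensemble_phi(ens, X, bg, forced)
        off = 0.5 * (plus - minus)
        off[:, i] = 0.0
        tensor[:, i, :] = off
    tensor = 0.5 * (tensor + tensor.transpose(0, 2, 1))
    idx = np.arange(d)
    tensor[:, idx, idx] = phi - tensor.sum(axis=2)
    base = float(np.mean(margin_from_leaves(ens, bg)))
    return InteractionTensor(tensor, list(model.features), base)


def brute_force_shapley(
    margin_fn: Callable[[np.ndarray], np.ndarray] | TrainedModel,
    subject: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """Exact Shapley values by coalition enumeration (<= 12 features).

    The value of a coalition S is the background-average of the margin with
    features in S fixed at the subject's values (the interventional
    convention).  Deterministic given the background sample.
    """
    if isinstance(margin_fn, TrainedModel):
        model = margin_fn
        margin_fn = lambda A: model.model.predict(A, output_margin=True)  # noqa: E731
    x = np.asarray(subject, dtype=np.float64).ravel()
    bg = np.asarray(background, dtype=np.float64)
    d = x.size
    if d > 12:
        raise ValueError("brute-force enumeration limited to 12 features")
    vals = {}
    for r in range(d + 1):
        for S in combinations(range(d), r):
            A = bg.copy()
            A[:, list(S)] = x[list(S)]
            vals[S] = float(np.mean(margin_fn(A)))
    phi = np.zeros(d)
    for k in range(d):
        others = [j for j in range(d) if j != k]
        for r in range(d):
            coef = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)
            for S in combinations(others, r):
                phi[k] += coef * (vals[tuple(sorted(S + (k,)))] - vals[S])
    return phi


def importance(attr: AttributionSet, model_tag: str | None = None) -> ImportanceRanking:
    """Global ranking by mean absolute attribution, ties lexicographic."""
    if attr.phi.empty:
        raise ValueError("empty attribution set")
    mean_abs = attr.phi.abs().mean(axis=0)
    order = sorted(mean_abs.index, key=lambda f: (-mean_abs[f], f))
    return ImportanceRanking(
        order, mean_abs[order].to_numpy(), model_tag or attr.model_tag
    )


def compare_rankings(
    ranking_a: ImportanceRanking | Sequence[str],
    ranking_b: ImportanceRanking | Sequence[str],
    universe: Sequence[str],
    k: int = 20,
) -> dict:
    """Top-k overlap statistics between two importance rankings.

    Both rankings are restricted to the shared feature universe, the top-k
    of each side defines a 2x2 membership table, and significance comes
    from the two-sided Fisher exact test (exact hypergeometric
    enumeration).  Spearman's rho compares the full rank vectors over the
    universe.
    """
    uni = list(universe)
    if k > len(uni):
        raise ValueError("k exceeds the shared universe size")
    order_a = [f for f in _order(ranking_a) if f in set(uni)]
    order_b = [f for f in _order(ranking_b) if f in set(uni)]
    if set(order_a) != set(uni) or set(order_b) != set(uni):
        raise ValueError("rankings must cover the shared universe")
    top_a, top_b = set(order_a[:k]), set(order_b[:k])
    overlap = len(top_a & top_b)
    n_uni = len(uni)
    table = [
        [overlap, k - overlap],
        [k - overlap, n_uni - 2 * k + overlap],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    rank_a = {f: i for i, f in enumerate(order_a)}
    rank_b = {f: i for i, f in enumerate(order_b)}
    rho, rho_p = spearmanr([rank_a[f] for f in uni], [rank_b[f] for f in uni])
    return {
        "overlap": overlap,
        "fisher_p": float(p),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "table": table,
    }


def _order(ranking) -> list[str]:
    return list(ranking.features) if isinstance(ranking, ImportanceRanking) else list(ranking)
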