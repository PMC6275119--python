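"""Monte Carlo feature selection with interdependency discovery.

Many decision trees are grown on random feature subsets ("projections");
each feature accumulates relative importance (RI) from the Gini impurity
decreases of the nodes that split on it, weighted by the tree's held-out
weighted accuracy (mean per-class recall) and by the fraction of training
samples reaching the node:

    RI_g = sum_trees (wAcc)^u * sum_{nodes splitting on g} IG(n) * (n_n / n_tree)^v

Pairs of features that co-occur on a decision path (ancestor -> descendant
split) accumulate interdependency (ID) strength IG(n) * (n_n / n_tree),
yielding a directed weighted graph over features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ContractError

logger = logging.getLogger(__name__)


@dataclass
class MCFSConfig:
    """Knobs of the Monte Carlo feature-selection procedure.

    ``s`` projections each draw ``ceil(m_frac * d)`` features; within a
    projection ``t`` stratified splits with training fraction ``split_frac``
    each grow one unpruned Gini tree (min leaf 2).  ``u``/``v`` are the
    wAcc and node-fraction exponents of the RI formula.
    """

    s: int = 1000
    m_frac: float = 0.25
    t: int = 5
    split_frac: float = 2 / 3
    u: float = 1.0
    v: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1 or self.t < 1:
            raise ContractError("s and t must be >= 1")
        if not 0 < self.m_frac <= 1:
            raise ContractError("m_frac must lie in (0, 1]")
        if not 0 < self.split_frac < 1:
            raise ContractError("split_frac must lie in (0, 1)")
        if self.u < 0 or self.v < 0:
            raise ContractError("u and v must be >= 0")


@dataclass
class MCFSResult:
    """Relative-importance ranking plus interdependency graph."""

    ri: pd.Series  # indexed by feature name, canonical order
    ranking: list[str]  # features by descending ri, ties by canonical order
    id_graph: dict[tuple[str, str], float]  # (ancestor, descendant) -> strength
    never_drawn: list[str] = field(default_factory=list)

    def ranking_frame(self, groups: dict[str, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "feature": self.ranking,
                "ri": [self.ri[f] for f in self.ranking],
            }
        )
        if groups:
            df.insert(2, "group", [groups.get(f, "") for f in self.ranking])
        return df

    def edges_frame(self, undirected: bool = False) -> pd.DataFrame:
        """Edge list; ``undirected`` sums strengths over both directions."""
        if undirected:
            merged: dict[tuple[str, str], float] = {}
            for (a, b), w in self.id_graph.items():
                key = (a, b) if a <= b else (b, a)
                merged[key] = merged.get(key, 0.0) + w
            items = merged.items()
        else:
            items = self.id_graph.items()
        rows = sorted(items, key=lambda kv: -kv[1])
        return pd.DataFrame(
            [(a, b, w) for (a, b), w in rows],
            columns=["feature_a", "feature_b", "strength"],
        )

    def to_tsv(self, path: str | Path, groups: dict[str, str] | None = None) -> None:
        self.ranking_frame(groups).to_csv(path, sep="\t", index=False)


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Per-class uniform train/test indices; both classes on both sides."""
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _weighted_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls over the classes present in y_true."""
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(recalls))


def _accumulate_tree(
    tree: DecisionTreeClassifier,
    feat_ids: np.ndarray,
    wacc: float,
    u: float,
    v: float,
    ri: np.ndarray,
    id_graph: dict[tuple[int, int], float],
) -> None:
    t = tree.tree_
    n_root = t.weighted_n_node_samples[0]
    wacc_u = wacc**u

    # iterative DFS carrying the list of ancestor split features
    stack: list[tuple[int, tuple[int, ...]]] = [(0, ())]
    while stack:
        node, ancestors = stack.pop()
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        g = feat_ids[t.feature[node]]
        n_n = t.weighted_n_node_samples[node]
        ig = (
            t.impurity[node]
            - (t.weighted_n_node_samples[left] / n_n) * t.impurity[left]
            - (t.weighted_n_node_samples[right] / n_n) * t.impurity[right]
        )
        frac = n_n / n_root
        ri[g] += wacc_u * ig * frac**v
        contrib = ig * frac
        for a in set(ancestors):
            if a != g:
                key = (a, g)
                id_graph[key] = id_graph.get(key, 0.0) + contrib
        child_anc = ancestors + (g,)
        stack.append((left, child_anc))
        stack.append((right, child_anc))


def run_mcfs(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    config: MCFSConfig,
    feature_names: Sequence[str] | None = None,
) -> MCFSResult:
    """Rank features by Monte Carlo relative importance.

    ``y`` is binary with both classes present; deterministic given
    ``config.seed``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if d < 2:
        raise ContractError("need at least 2 features")
    if n < 10:
        raise ContractError("need at least 10 rows")
    if len(np.unique(y)) < 2:
        raise ContractError("y must contain both classes")
    feature_names = list(feature_names) if feature_names else [f"f{i}" for i in range(d)]
    if len(feature_names) != d:
        raise ContractError("feature_names length mismatch")

    m = math.ceil(config.m_frac * d)
    if m < 1:
        raise ContractError("m_frac too small: no features per projection")

    rng = np.random.default_rng(config.seed)
    ri = np.zeros(d)
    id_graph_ids: dict[tuple[int, int], float] = {}
    drawn = np.zeros(d, dtype=bool)

    for _ in range(config.s):
        feats = np.sort(rng.choice(d, size=m, replace=False))
        drawn[feats] = True
        Xp = X[:, feats]
        for _ in range(config.t):
            tr, te = _stratified_split(y, config.split_frac, rng)
            tree = DecisionTreeClassifier(
                criterion="gini",
                min_samples_leaf=2,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(Xp[tr], y[tr])
            wacc = _weighted_accuracy(y[te], tree.predict(Xp[te]))
            _accumulate_tree(tree, feats, wacc, config.u, config.v, ri, id_graph_ids)

    never = [feature_names[i] for i in np.flatnonzero(~drawn)]
    if never:
        logger.warning("run_mcfs: %d features never drawn in any projection", len(never))

    order = sorted(range(d), key=lambda i: (-ri[i], i))  # ties: canonical order
    ranking = [feature_names[i] for i in order]
    id_graph = {
        (feature_names[a], feature_names[b]): w for (a, b), w in id_graph_ids.items()
    }
    return MCFSResult(
        ri=pd.Series(ri, index=feature_names),
        ranking=ranking,
        id_graph=id_graph,
        never_drawn=never,
    )


def top_features(result: MCFSResult, k: int) -> list[str]:
    """First ``k`` features of the ranking (ties already canonical)."""
    d = len(result.ranking)
    if not 1 <= k <= d:
        raise ContractError(f"k must lie in [1, {d}], got {k}")
    return result.ranking[:k]
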