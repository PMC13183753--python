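"""Regression-tree ensemble with mean-decrease-impurity feature importance.

CART regression trees grown by greedy variance reduction over a random
feature subset per node.  Node k splitting on feature j contributes

    F_jk = W_k C_k - W_left C_left - W_right C_right,

where W is the fraction of training samples reaching the node and C is
the node impurity (mean squared deviation of its targets).  Per-tree
importances are F_j = sum_k F_jk / sum_h F_h over all internal nodes,
so they sum to one; the forest importance is the unweighted mean across
trees.  Profile hyperparameters: batch printer 400 trees / depth 160 /
2 features per split / min-split 4 / min-leaf 1; continuous printer
2000 trees / depth 50 / 4 features per split / min-split 12 / min-leaf 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import FEATURE_NAMES

__all__ = [
    "ForestConfig",
    "TreeNode",
    "RegressionTree",
    "RandomForest",
    "fit_tree",
    "node_importance",
    "tree_importance",
    "forest_importance",
    "BATCH_FOREST",
    "CONTINUOUS_FOREST",
]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 400
    max_depth: int = 160
    max_features: int = 2
    min_samples_split: int = 4
    min_samples_leaf: int = 1
    bootstrap: bool = True

    def __post_init__(self) -> None:
        for name in ("n_trees", "max_depth", "max_features",
                     "min_samples_split", "min_samples_leaf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


#: per-printer profiles
BATCH_FOREST = ForestConfig(n_trees=400, max_depth=160, max_features=2,
                            min_samples_split=4, min_samples_leaf=1)
CONTINUOUS_FOREST = ForestConfig(n_trees=2000, max_depth=50, max_features=4,
                                 min_samples_split=12, min_samples_leaf=3)


@dataclass
class TreeNode:
    """One node of a regression tree.

    ``weight`` is the fraction of the tree's training samples reaching the
    node; ``impurity`` is the mean squared deviation of its targets.
    """

    weight: float
    impurity: float
    value: float                     # mean target (leaf prediction)
    n_samples: int
    feature: int | None = None       # split feature, None for a leaf
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    sample_idx: np.ndarray | None = None  # kept when store_samples=True

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    root: TreeNode
    n_features: int

    def internal_nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.left, node.right])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.value
        return out

    def max_depth(self) -> int:
        def depth(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(depth(node.left), depth(node.right))
        return depth(self.root)


def _best_split(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray,
    features: np.ndarray, min_leaf: int,
) -> tuple[int, float, np.ndarray, np.ndarray] | None:
    """Exhaustive scan for the variance-minimizing split.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values.  Ties break toward the lowest feature index then the lowest
    threshold (features are scanned in ascending index order and only a
    strictly better score replaces the incumbent).
    """
    m = idx.size
    y_node = y[idx]
    best = None
    best_score = np.inf
    for f in np.sort(features):
        v = X[idx, f]
        order = np.argsort(v, kind="mergesort")
        sv = v[order]
        sy = y_node[order]
        csum = np.cumsum(sy)
        csq = np.cumsum(sy * sy)
        total_sum, total_sq = csum[-1], csq[-1]
        # split after position i (1-based left size)
        sizes = np.arange(1, m)
        valid = (sv[1:] > sv[:-1]) & (sizes >= min_leaf) & (m - sizes >= min_leaf)
        if not valid.any():
            continue
        ls = csum[:-1][valid]
        lq = csq[:-1][valid]
        nl = sizes[valid].astype(float)
        nr = m - nl
        # total child SSE; parent SSE constant within a node
        score = (lq - ls**2 / nl) + ((total_sq - lq) - (total_sum - ls) ** 2 / nr)
        j = int(np.argmin(score))
        if score[j] < best_score - 1e-15:
            pos = np.flatnonzero(valid)[j]
            thr = 0.5 * (sv[pos] + sv[pos + 1])
            left_mask = v <= thr
            best = (f, float(thr), idx[left_mask], idx[~left_mask])
            best_score = score[j]
    return best


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig,
    rng: np.random.Generator | int | None = None,
    store_samples: bool = False,
) -> RegressionTree:
    """Grow one CART regression tree honoring the config constraints."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n, p = X.shape
    k = min(config.max_features, p)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y_node = y[idx]
        node = TreeNode(
            weight=idx.size / n,
            impurity=float(np.var(y_node)),
            value=float(y_node.mean()),
            n_samples=idx.size,
            sample_idx=idx.copy() if store_samples else None,
        )
        if (depth >= config.max_depth
                or idx.size < config.min_samples_split
                or node.impurity <= 1e-18):
            return node
        features = rng.choice(p, size=k, replace=False)
        split = _best_split(X, y, idx, features, config.min_samples_leaf)
        if split is None:
            return node
        f, thr, left_idx, right_idx = split
        node.feature = int(f)
        node.threshold = thr
        node.left = build(left_idx, depth + 1)
        node.right = build(right_idx, depth + 1)
        return node

    return RegressionTree(root=build(np.arange(n), 0), n_features=p)


def node_importance(node: TreeNode) -> float:
    """Weighted impurity decrease F_jk of an internal node."""
    if node.is_leaf:
        raise ValueError("leaf nodes carry no split importance")
    return (node.weight * node.impurity
            - node.left.weight * node.left.impurity
            - node.right.weight * node.right.impurity)


def tree_importance(tree: RegressionTree) -> np.ndarray:
    """Per-feature importances of one tree, normalized to sum to 1."""
    raw = np.zeros(tree.n_features)
    for node in tree.internal_nodes():
        raw[node.feature] += node_importance(node)
    total = raw.sum()
    if total <= 0:
        warnings.warn("tree has no informative splits; importances are zero")
        return raw
    return raw / total


@dataclass
class RandomForest:
    trees: list[RegressionTree]
    config: ForestConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.mean([t.predict(X) for t in self.trees], axis=0)


def forest_importance(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig = BATCH_FOREST,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, RandomForest]:
    """Mean of per-tree MDI importance vectors over a bootstrap forest."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = X.shape[0]
    trees, vectors = [], []
    for _ in range(config.n_trees):
        if config.bootstrap:
            idx = rng.integers(0, n, size=n)
            tree = fit_tree(X[idx], y[idx], config, rng)
        else:
            tree = fit_tree(X, y, config, rng)
        trees.append(tree)
        vectors.append(tree_importance(tree))
    importance = np.mean(vectors, axis=0)
    return importance, RandomForest(trees=trees, config=config)
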