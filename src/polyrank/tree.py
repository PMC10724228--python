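"""Regression-tree factor analysis of the degradability score.

A CART-style regression tree maps the nine functional-group counts to the
learned degradability score d, exposing which structural features the
ranking model responds to.  Splits are greedy variance-reduction splits on
integer thresholds ("count <= t" vs "count > t"); growth is best-first up to
``max_leaves``.  Ties in split gain break on the fixed descriptor order
(ester, alkyl_carbon, hydroxyl, ether, benzene_ring, amide, carbonate,
heteroatom, urethane), then on the smaller threshold, making refits
deterministic under any row permutation.

Leaves are then sorted by their mean score d̄ and partitioned into three
categories — "undegradable" / "middle" / "degradable" — at the two largest
gaps between consecutive leaf means.
"""
from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ConfigurationError, ValidationError
from .featurize import DESCRIPTOR_NAMES

_GAIN_EPS = 1e-12


@dataclass
class Node:
    """Internal node (feature/threshold set) or leaf (mean/members set)."""

    indices: np.ndarray  # row indices (original order) reaching this node
    mean: float
    sse: float
    depth: int
    feature: int | None = None
    threshold: int | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return self.indices.size


def _node_stats(y: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    mean = float(y[idx].mean())
    return mean, float(((y[idx] - mean) ** 2).sum())


def _best_split(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, min_leaf_size: int
) -> tuple[float, int, int] | None:
    """Best (gain, feature, threshold) under the deterministic tie-break.

    Features are scanned in the fixed descriptor order and thresholds in
    increasing order; a candidate replaces the incumbent only on a strictly
    larger gain, so earlier features / smaller thresholds win ties.
    """
    _, parent_sse = _node_stats(y, idx)
    best: tuple[float, int, int] | None = None
    for j in range(X.shape[1]):
        col = X[idx, j]
        for thr in np.unique(col)[:-1]:
            mask = col <= thr
            n_left = int(mask.sum())
            if n_left < min_leaf_size or idx.size - n_left < min_leaf_size:
                continue
            left, right = idx[mask], idx[~mask]
            gain = parent_sse - _node_stats(y, left)[1] - _node_stats(y, right)[1]
            if best is None or gain > best[0] + _GAIN_EPS:
                best = (gain, j, int(thr))
    if best is None or best[0] <= _GAIN_EPS:
        return None
    return best


class DegradabilityTree(RegressorMixin, BaseEstimator):
    """CART-style regression tree over integer descriptor counts.

    Parameters
    ----------
    max_leaves : int
        Best-first growth stops when this many leaves exist (default 10,
        matching the leaf count used in the factor analysis of the study
        datasets).
    min_leaf_size : int
        Minimum samples per leaf.
    feature_names : sequence of str, optional
        Defaults to the nine descriptor names.
    """

    def __init__(
        self,
        max_leaves: int = 10,
        min_leaf_size: int = 1,
        feature_names: Sequence[str] | None = None,
    ):
        self.max_leaves = max_leaves
        self.min_leaf_size = min_leaf_size
        self.feature_names = feature_names

    def fit(self, X, y):
        if self.max_leaves < 1:
            raise ConfigurationError("max_leaves must be >= 1")
        X, y = check_X_y(X, y, ensure_min_samples=2)
        names = (
            tuple(self.feature_names)
            if self.feature_names is not None
            else DESCRIPTOR_NAMES[: X.shape[1]]
        )
        if len(names) != X.shape[1]:
            raise ConfigurationError(
                f"{len(names)} feature names for {X.shape[1]} columns"
            )
        # canonical row order makes every sum permutation-invariant
        order = np.lexsort(tuple(X[:, j] for j in reversed(range(X.shape[1]))) + (y,))
        Xs, ys = X[order], y[order]
        mean, sse = _node_stats(ys, np.arange(len(ys)))
        root = Node(indices=np.arange(len(ys)), mean=mean, sse=sse, depth=0)
        if np.ptp(X, axis=0).max(initial=0) == 0 and np.ptp(y) > 0:
            warnings.warn(
                "descriptors are constant but scores are not: single-leaf tree",
                stacklevel=2,
            )
        heap: list[tuple[float, int, Node]] = []
        counter = 0

        def push(node: Node) -> None:
            nonlocal counter
            split = _best_split(Xs, ys, node.indices, self.min_leaf_size)
            if split is not None:
                heapq.heappush(heap, (-split[0], counter, node))
                node._pending = split  # type: ignore[attr-defined]
                counter += 1

        push(root)
        n_leaves = 1
        while heap and n_leaves < self.max_leaves:
            _, _, node = heapq.heappop(heap)
            gain, j, thr = node._pending  # type: ignore[attr-defined]
            mask = Xs[node.indices, j] <= thr
            li, ri = node.indices[mask], node.indices[~mask]
            node.feature, node.threshold = j, thr
            lm, ls = _node_stats(ys, li)
            rm, rs = _node_stats(ys, ri)
            node.left = Node(indices=li, mean=lm, sse=ls, depth=node.depth + 1)
            node.right = Node(indices=ri, mean=rm, sse=rs, depth=node.depth + 1)
            n_leaves += 1
            push(node.left)
            push(node.right)

        self.tree_ = root
        self.feature_names_ = names
        self.n_features_in_ = X.shape[1]
        self._row_order_ = order  # canonical -> original row mapping
        leaves = []

        def collect(node: Node) -> None:
            if node.is_leaf:
                node.leaf_id = len(leaves)
                # report membership in the caller's row numbering
                node.indices = np.sort(order[node.indices])
                leaves.append(node)
            else:
                collect(node.left)
                collect(node.right)

        collect(root)
        self.leaves_ = leaves
        self.n_leaves_ = len(leaves)
        return self

    # -- inference --------------------------------------------------------
    def _route(self, x: np.ndarray) -> Node:
        node = self.tree_
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = check_array(X)
        return np.array([self._route(x).mean for x in X])

    def apply(self, X) -> np.ndarray:
        """Leaf id reached by each row."""
        check_is_fitted(self, "tree_")
        X = check_array(X)
        return np.array([self._route(x).leaf_id for x in X])

    def explain(self, x) -> list[tuple[str, int, str]]:
        """Decision path for one sample: [(feature, threshold, branch), ...]."""
        check_is_fitted(self, "tree_")
        x = np.asarray(x).ravel()
        path = []
        node = self.tree_
        while not node.is_leaf:
            went_left = x[node.feature] <= node.threshold
            path.append(
                (self.feature_names_[node.feature], int(node.threshold), "<=" if went_left else ">")
            )
            node = node.left if went_left else node.right
        return path

    @property
    def leaf_means_(self) -> np.ndarray:
        return np.array([leaf.mean for leaf in self.leaves_])

    @property
    def split_features_(self) -> list[str]:
        """Feature names used at internal nodes (with multiplicity, preorder)."""
        out: list[str] = []

        def walk(node: Node) -> None:
            if not node.is_leaf:
                out.append(self.feature_names_[node.feature])
                walk(node.left)
                walk(node.right)

        walk(self.tree_)
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "tree_")

        def conv(node: Node) -> dict:
            if node.is_leaf:
                return {
                    "leaf_id": node.leaf_id,
                    "n": int(node.n),
                    "mean": node.mean,
                    "members": [int(i) for i in node.indices],
                }
            return {
                "feature": self.feature_names_[node.feature],
                "threshold": int(node.threshold),
                "n": int(node.n),
                "left": conv(node.left),
                "right": conv(node.right),
            }

        return {"max_leaves": self.max_leaves, "tree": conv(self.tree_)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def render_text(self, labels: Sequence[str] | None = None) -> str:
        """Indented text rendering; ``labels`` names the training rows."""
        check_is_fitted(self, "tree_")
        lines: list[str] = []

        def walk(node: Node, indent: str) -> None:
            if node.is_leaf:
                members = (
                    ", ".join(labels[i] for i in node.indices) if labels is not None else f"n={node.n}"
                )
                lines.append(f"{indent}leaf {node.leaf_id}: d̄={node.mean:.4f} [{members}]")
            else:
                name = self.feature_names_[node.feature]
                lines.append(f"{indent}{name} <= {node.threshold}:")
                walk(node.left, indent + "  ")
                lines.append(f"{indent}{name} > {node.threshold}:")
                walk(node.right, indent + "  ")

        walk(self.tree_, "")
        return "\n".join(lines)


def fit_tree(
    descriptors: np.ndarray,
    scores: Sequence[float],
    max_leaves: int = 10,
    min_leaf_size: int = 1,
    feature_names: Sequence[str] | None = None,
) -> DegradabilityTree:
    """Functional wrapper over :class:`DegradabilityTree`."""
    return DegradabilityTree(
        max_leaves=max_leaves, min_leaf_size=min_leaf_size, feature_names=feature_names
    ).fit(np.asarray(descriptors), np.asarray(scores, dtype=float))


@dataclass(frozen=True)
class CategoryRule:
    """Two boundaries on leaf means defining the three degradability bands."""

    boundaries: tuple[float, float]
    leaf_categories: dict[int, str]  # leaf_id -> label
    provenance: str = "derived-from-fit"

    LABELS = ("undegradable", "middle", "degradable")


def categorize_leaves(
    tree: DegradabilityTree, method: str = "largest-gaps"
) -> CategoryRule:
    """Partition leaves into undegradable/middle/degradable bands.

    Leaves are sorted by mean score; the two largest gaps between
    consecutive means define the three groups, and the reported boundaries
    are the gap midpoints.  (For well-separated leaf-mean clusters this is
    the 3-group 1-d partition of minimum within-group variance.)
    """
    if method != "largest-gaps":
        raise ConfigurationError(f"unknown method {method!r}")
    check_is_fitted(tree, "tree_")
    means = tree.leaf_means_
    if means.size < 3:
        raise ValidationError(
            f"need >= 3 leaves to form three categories, have {means.size}; "
            "use a single- or two-category fallback instead"
        )
    order = np.argsort(means, kind="stable")
    sorted_means = means[order]
    gaps = np.diff(sorted_means)
    # two largest gaps; ties resolved toward the leftmost gap
    ranked = sorted(range(gaps.size), key=lambda i: (-gaps[i], i))
    cut_positions = sorted(ranked[:2])
    boundaries = tuple(
        float((sorted_means[i] + sorted_means[i + 1]) / 2) for i in cut_positions
    )
    categories: dict[int, str] = {}
    for pos, leaf_idx in enumerate(order):
        band = sum(pos > cut for cut in cut_positions)
        categories[int(tree.leaves_[leaf_idx].leaf_id)] = CategoryRule.LABELS[band]
    return CategoryRule(boundaries=boundaries, leaf_categories=categories)
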