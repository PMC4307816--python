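"""A small deterministic CART for binary classification.

Binary axis-aligned threshold splits chosen by Gini impurity. Determinism
is contractual for game scoring: among equally impure splits the lowest
feature index wins, then the lowest threshold; leaf-prediction ties go to
class 0. Thresholds are midpoints between consecutive distinct values,
with the ``<= threshold`` branch on the left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class TreeNode:
    """Internal node (feature/threshold set) or leaf (prediction set)."""

    prediction: Optional[int] = None
    n_samples: int = 0
    class_counts: tuple[int, int] = (0, 0)
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> Optional[tuple[int, float, float]]:
    """Lowest-weighted-Gini split; ties -> lowest feature, lowest threshold.

    Returns (feature, threshold, weighted_gini) or None if no valid split
    reduces impurity. Evaluated for all features at once: candidate cuts
    sit between consecutive distinct sorted values.
    """
    n = len(y)
    total1 = float(y.sum())
    parent = 2.0 * (total1 / n) * (1.0 - total1 / n)
    order = np.argsort(X, axis=0, kind="stable")          # (n, f)
    xs = np.take_along_axis(X, order, axis=0)
    cum1 = np.cumsum(y[order], axis=0, dtype=float)       # class-1 left counts
    n_left = np.arange(1, n, dtype=float)[:, None]        # cut after row i
    valid = xs[:-1] < xs[1:]
    if min_leaf > 1:
        valid = valid.copy()
        valid[: min_leaf - 1] = False
        valid[n - min_leaf:] = False
    if not valid.any():
        return None
    n_right = n - n_left
    n1_left = cum1[:-1]
    n1_right = total1 - n1_left
    p_l = n1_left / n_left
    p_r = n1_right / n_right
    gini = (n_left * 2.0 * p_l * (1.0 - p_l)
            + n_right * 2.0 * p_r * (1.0 - p_r)) / n
    gini = np.where(valid, gini, np.inf)
    eps = 1e-12
    best_gini = gini.min()
    if not best_gini < parent - eps:
        return None
    # tie-break: lowest feature index, then lowest threshold
    thresholds = (xs[:-1] + xs[1:]) / 2.0
    tied = gini <= best_gini + eps
    for j in range(X.shape[1]):
        col = tied[:, j]
        if col.any():
            thr = thresholds[:, j][col].min()
            return j, float(thr), float(best_gini)
    return None  # pragma: no cover


def _build(
    X: np.ndarray, y: np.ndarray, depth: int,
    max_depth: Optional[int], min_leaf: int,
) -> TreeNode:
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    node = TreeNode(n_samples=len(y), class_counts=(n0, n1))
    pure = n0 == 0 or n1 == 0
    at_depth = max_depth is not None and depth >= max_depth
    if pure or at_depth or len(y) < 2 * min_leaf:
        node.prediction = 1 if n1 > n0 else 0
        return node
    split = _best_split(X, y, min_leaf)
    if split is None:
        node.prediction = 1 if n1 > n0 else 0
        return node
    j, thr, _ = split
    node.feature, node.threshold = j, thr
    mask = X[:, j] <= thr
    node.left = _build(X[mask], y[mask], depth + 1, max_depth, min_leaf)
    node.right = _build(X[~mask], y[~mask], depth + 1, max_depth, min_leaf)
    return node


class DecisionTree:
    """Deterministic Gini CART over real-valued features.

    Parameters
    ----------
    max_depth : maximum number of split levels (None = unlimited).
    min_leaf : minimum samples on each side of a split.
    """

    def __init__(self, max_depth: Optional[int] = 3, min_leaf: int = 5):
        if min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.root: Optional[TreeNode] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DecisionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, n_features) matching y")
        self.root = _build(X, y, 0, self.max_depth, self.min_leaf)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.root is None:
            raise RuntimeError("tree is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=int)

        def walk(node: TreeNode, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = node.prediction
                return
            left = X[idx, node.feature] <= node.threshold
            walk(node.left, idx[left])
            walk(node.right, idx[~left])

        walk(self.root, np.arange(len(X)))
        return out

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    # -- exports ---------------------------------------------------------

    def to_text(self, feature_names: Sequence[str]) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(
                    f"{pad}class {node.prediction} "
                    f"(n={node.n_samples}, counts={node.class_counts})"
                )
            else:
                name = feature_names[node.feature]
                lines.append(f"{pad}{name} <= {node.threshold:g}")
                walk(node.left, indent + 1)
                lines.append(f"{pad}{name} > {node.threshold:g}")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def to_dot(self, feature_names: Sequence[str]) -> str:
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: TreeNode) -> int:
            my_id = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lines.append(
                    f'  n{my_id} [label="class {node.prediction}\\n'
                    f'n={node.n_samples}"];'
                )
            else:
                name = feature_names[node.feature]
                lines.append(f'  n{my_id} [label="{name} <= {node.threshold:g}"];')
                left_id = walk(node.left)
                right_id = walk(node.right)
                lines.append(f'  n{my_id} -> n{left_id} [label="yes"];')
                lines.append(f'  n{my_id} -> n{right_id} [label="no"];')
            return my_id

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)

    def internal_features(self) -> set[int]:
        """Indices of features used at internal nodes."""
        found: set[int] = set()

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                found.add(node.feature)
                walk(node.left)
                walk(node.right)

        if self.root is not None:
            walk(self.root)
        return found
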