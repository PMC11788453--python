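"""Classification tree (CART) with Gini impurity and midpoint splits.

Grown on the drug x category reporting-ratio matrix with SOM unit numbers
as class labels, the tree turns an unsupervised clustering into a small
set of human-readable screening rules ("type 1 diabetes mellitus share
below 2.6% -> the low-volume profile group").  With only a handful of
rows the usual forest-scale guardrails are counterproductive, so the
defaults allow splitting down to single-row leaves and there is no
complexity-parameter pruning.

Split convention: thresholds are midpoints of adjacent distinct observed
values; a row goes left when ``value < threshold``.  Exact ties in
impurity decrease resolve by feature order (default: the *last* tying
feature in the fixed category order), then by the smallest threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._util import round_half_up
from .tables import RatioMatrix

__all__ = ["CartConfig", "TreeNode", "gini", "best_split", "grow", "extract_rules"]

_EPS = 1e-12


@dataclass(frozen=True)
class CartConfig:
    min_split: int = 2   # smallest node size on which a split is attempted
    min_bucket: int = 1  # smallest admissible leaf size
    max_depth: Optional[int] = None
    tie_break: str = "last-feature"  # "first-feature" | "last-feature"

    def __post_init__(self) -> None:
        if self.min_bucket < 1:
            raise ValueError("min_bucket must be >= 1")
        if self.min_split < 2:
            raise ValueError("min_split must be >= 2")
        if self.tie_break not in ("first-feature", "last-feature"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.min_split < 2 * self.min_bucket:
            warnings.warn(
                f"min_split={self.min_split} < 2*min_bucket={2 * self.min_bucket}: "
                "some admissible nodes cannot be split"
            )


@dataclass
class TreeNode:
    """One node: class counts plus either a split or a leaf label."""

    class_counts: dict
    members: list[str]  # row names reaching this node
    depth: int = 0
    split_feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None   # rows with value < threshold
    right: Optional["TreeNode"] = None  # rows with value >= threshold
    leaf_label: Optional[object] = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def predict_one(self, x: dict) -> object:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.split_feature] < node.threshold else node.right
        return node.leaf_label

    def to_dict(self) -> dict:
        d = {"n": self.n, "class_counts": {str(k): v for k, v in self.class_counts.items()},
             "members": self.members, "depth": self.depth}
        if self.is_leaf:
            d["leaf_label"] = self.leaf_label
        else:
            d.update(split_feature=self.split_feature, threshold=self.threshold,
                     threshold_display=round_half_up(self.threshold, 1),
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def gini(class_counts) -> float:
    """Gini impurity 1 - sum_k (n_k/n)^2 of a count vector or mapping."""
    counts = np.asarray(
        list(class_counts.values()) if hasattr(class_counts, "values") else class_counts,
        dtype=float,
    )
    if np.any(counts < 0):
        raise ValueError("negative class count")
    n = counts.sum()
    if n == 0:
        raise ValueError("all-zero class counts")
    p = counts / n
    return float(1.0 - np.sum(p * p))


@dataclass(frozen=True)
class Split:
    feature: str
    feature_index: int
    threshold: float
    decrease: float


def _counts(labels: Sequence) -> dict:
    out: dict = {}
    for y in labels:
        out[y] = out.get(y, 0) + 1
    return out


def best_split(
    X: np.ndarray,
    labels: Sequence,
    feature_names: Sequence[str],
    config: CartConfig = CartConfig(),
) -> Optional[Split]:
    """Exhaustive search over every feature and adjacent-value midpoint.

    Maximizes the weighted Gini decrease subject to ``min_bucket``;
    returns ``None`` when no admissible split improves impurity.  Exact
    ties resolve by ``tie_break`` feature order, then smallest threshold.
    """
    X = np.asarray(X, dtype=float)
    n = len(labels)
    if X.shape != (n, len(feature_names)):
        raise ValueError("X shape does not match labels/feature_names")
    if n < config.min_split:
        return None
    parent = gini(_counts(labels))
    labels = list(labels)
    best: Optional[Split] = None
    for j, fname in enumerate(feature_names):
        vals = X[:, j]
        uniq = np.unique(vals)
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            thr = (float(lo) + float(hi)) / 2.0
            mask = vals < thr
            nl = int(mask.sum())
            nr = n - nl
            if nl < config.min_bucket or nr < config.min_bucket:
                continue
            gl = gini(_counts([labels[i] for i in range(n) if mask[i]]))
            gr = gini(_counts([labels[i] for i in range(n) if not mask[i]]))
            dec = parent - (nl / n) * gl - (nr / n) * gr
            if dec <= _EPS:
                continue
            cand = Split(fname, j, thr, dec)
            if best is None or dec > best.decrease + _EPS:
                best = cand
            elif abs(dec - best.decrease) <= _EPS:
                if config.tie_break == "last-feature" and j > best.feature_index:
                    best = cand
                elif j == best.feature_index and thr < best.threshold:
                    best = cand
                # first-feature: keep the earlier feature / smaller threshold
    return best


def grow(
    data: Union[RatioMatrix, np.ndarray],
    labels: Sequence,
    config: CartConfig = CartConfig(),
    feature_names: Optional[Sequence[str]] = None,
    row_names: Optional[Sequence[str]] = None,
) -> TreeNode:
    """Recursive binary splitting until pure, too small, or unimprovable."""
    if isinstance(data, RatioMatrix):
        X = data.values
        feature_names = list(data.features)
        row_names = list(data.drugs)
    else:
        X = np.asarray(data, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        if row_names is None:
            row_names = [f"r{i}" for i in range(X.shape[0])]
    labels = list(labels)
    if len(labels) != X.shape[0] or len(labels) < 1:
        raise ValueError("labels must match the number of data rows (>= 1)")

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        ys = [labels[i] for i in idx]
        node = TreeNode(class_counts=_counts(ys),
                        members=[row_names[i] for i in idx], depth=depth)
        pure = len(set(ys)) == 1
        depth_ok = config.max_depth is None or depth < config.max_depth
        if not pure and depth_ok and len(idx) >= config.min_split:
            sp = best_split(X[idx], ys, feature_names, config)
            if sp is not None:
                mask = X[idx, sp.feature_index] < sp.threshold
                node.split_feature = sp.feature
                node.threshold = sp.threshold
                node.left = build(idx[mask], depth + 1)
                node.right = build(idx[~mask], depth + 1)
                return node
        # majority class; ties by first occurrence among the node's rows
        node.leaf_label = max(node.class_counts, key=node.class_counts.get)
        return node

    return build(np.arange(X.shape[0]), 0)


def extract_rules(tree: TreeNode) -> list[str]:
    """One textual rule per leaf: the path conjunction and the leaf class.

    Thresholds are rendered at full precision with a display form rounded
    half-up to one decimal, e.g. ``Type 1 diabetes mellitus < 2.55
    (display 2.6)``.
    """
    rules: list[str] = []

    def walk(node: TreeNode, conds: list[str]) -> None:
        if node.is_leaf:
            body = " AND ".join(conds) if conds else "always"
            members = ", ".join(sorted(node.members))
            rules.append(f"IF {body} THEN unit {node.leaf_label} ({members})")
            return
        disp = round_half_up(node.threshold, 1)
        walk(node.left, conds + [f"{node.split_feature} < {node.threshold!r} (display {disp})"])
        walk(node.right, conds + [f"{node.split_feature} >= {node.threshold!r} (display {disp})"])

    walk(tree, [])
    return rules
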