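"""Depth-2 recursive partitioning (CART) for RP-symptom classification.

Greedy binary splits minimising Gini impurity with equal misclassification
costs, candidate thresholds at midpoints of consecutive sorted unique values,
maximum depth 2 and a minimum leaf size of 5.  Leaves predict their majority
class (ties classified symptomatic).  Written from first principles so the
induced rule — typically "symptomatic iff SUV95 > a or V30 > b" — is exposed
directly rather than buried in a generic estimator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_DEPTH = 2
MIN_LEAF = 5


@dataclass
class _Node:
    prediction: bool
    variable: str | None = None
    threshold: float | None = None
    left: "_Node | None" = None          # x <= threshold
    right: "_Node | None" = None         # x > threshold

    @property
    def is_leaf(self) -> bool:
        return self.variable is None


@dataclass(frozen=True)
class PartitionSplit:
    variable: str
    threshold: float
    depth: int
    symptomatic_side: str                # "above" or "below"


@dataclass
class PartitionTree:
    """Fitted classification tree plus its training operating point."""

    root: _Node
    splits: list[PartitionSplit] = field(default_factory=list)
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    n: int = 0
    predictors: tuple[str, ...] = ()

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(records), dtype=bool)
        for i, (_, row) in enumerate(records.iterrows()):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.variable] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def rule_description(self) -> str:
        if self.root.is_leaf:
            cls = "symptomatic" if self.root.prediction else "asymptomatic"
            return f"single leaf: classify everyone {cls}"
        parts = [f"{s.variable} > {s.threshold:.4g} ({s.symptomatic_side} side symptomatic)"
                 for s in self.splits]
        return "; ".join(parts)


def _gini(n_pos: float, n_tot: float) -> float:
    if n_tot == 0:
        return 0.0
    p = n_pos / n_tot
    return 2.0 * p * (1.0 - p)


def _best_split(x_cols: dict[str, np.ndarray], y: np.ndarray, idx: np.ndarray,
                min_leaf: int):
    """Best (variable, threshold) by weighted-Gini reduction on rows ``idx``."""
    y_sub = y[idx]
    n = y_sub.size
    parent = _gini(y_sub.sum(), n) * n
    best = None
    for var, x in x_cols.items():
        xs = x[idx]
        order = np.argsort(xs, kind="stable")
        xs_sorted, ys_sorted = xs[order], y_sub[order]
        distinct = np.nonzero(np.diff(xs_sorted) > 0)[0]   # split after position i
        if distinct.size == 0:
            continue
        cum_pos = np.cumsum(ys_sorted)
        total_pos = cum_pos[-1]
        for i in distinct:
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            left_pos = cum_pos[i]
            cost = _gini(left_pos, n_left) * n_left \
                + _gini(total_pos - left_pos, n_right) * n_right
            if cost < parent - 1e-12 and (best is None or cost < best[0] - 1e-12):
                threshold = 0.5 * (xs_sorted[i] + xs_sorted[i + 1])
                best = (cost, var, float(threshold))
    return best


def _majority(y_sub: np.ndarray) -> bool:
    # ties classified symptomatic: never miss a potential RP case on a coin flip
    return bool(y_sub.sum() * 2 >= y_sub.size)


def recursive_partition(records: pd.DataFrame,
                        predictors=("suv_95", "v30"),
                        outcome: str = "symptomatic",
                        max_depth: int = MAX_DEPTH,
                        min_leaf: int = MIN_LEAF) -> PartitionTree:
    """Fit the depth-limited classification tree.

    Returns a single-leaf majority tree when no split reduces impurity (or a
    class is absent); that is not an error.
    """
    data = records[list(predictors) + [outcome]].dropna()
    if len(data) < 20:
        raise ValueError(f"need >= 20 complete records, got {len(data)}")
    y = data[outcome].astype(int).to_numpy()
    x_cols = {v: data[v].astype(float).to_numpy() for v in predictors}
    splits: list[PartitionSplit] = []

    def build(idx: np.ndarray, depth: int) -> _Node:
        y_sub = y[idx]
        node = _Node(prediction=_majority(y_sub))
        if depth >= max_depth or y_sub.size < 2 * min_leaf or y_sub.min() == y_sub.max():
            return node
        found = _best_split(x_cols, y, idx, min_leaf)
        if found is None:
            return node
        _, var, thr = found
        node.variable, node.threshold = var, thr
        below = x_cols[var][idx] <= thr
        node.left = build(idx[below], depth + 1)
        node.right = build(idx[~below], depth + 1)
        side = "above" if node.right.prediction and not node.left.prediction else \
               ("below" if node.left.prediction and not node.right.prediction else "mixed")
        splits.append(PartitionSplit(var, thr, depth + 1, side))
        return node

    root = build(np.arange(len(data)), 0)
    splits.sort(key=lambda s: s.depth)
    tree = PartitionTree(root=root, splits=splits, n=len(data),
                         predictors=tuple(predictors))
    pred = tree.predict(data)
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    tree.sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    tree.specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return tree
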