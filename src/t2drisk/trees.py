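"""C4.5-style decision trees with gain-ratio splits.

Only what the variable-selection stage needs: unpruned binary trees on
continuous (and 0/1-coded) predictors, grown by maximizing the gain ratio
(information gain divided by split information, base-2 entropy) over
candidate thresholds placed at midpoints between sorted distinct values.
Growth stops on purity, minimum node size, or maximum depth.  No pruning,
no fractional splits for missing values, no rule post-processing.

Trees exist here to be *counted over*: the selection rule tallies how often
each variable appears as a split in the shallow levels of many trees, and
the glycemia cut-point is read off the modal glucose threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-12


@dataclass
class DecisionTreeNode:
    """One node of an unpruned C4.5 tree.  Root has ``depth`` 1.

    Internal nodes carry ``split_variable``/``split_threshold`` and two
    children (left: value <= threshold, right: value > threshold); leaves
    carry only the majority ``class_label``.
    """

    depth: int
    n: int
    class_counts: tuple[int, int]
    class_label: int
    split_variable: str | None = None
    split_threshold: float | None = None
    children: list["DecisionTreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def to_dict(self) -> dict:
        d = {
            "depth": self.depth,
            "n": self.n,
            "class_counts": list(self.class_counts),
            "class_label": int(self.class_label),
        }
        if not self.is_leaf:
            d["split_variable"] = self.split_variable
            d["split_threshold"] = self.split_threshold
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTreeNode":
        node = cls(
            depth=d["depth"], n=d["n"],
            class_counts=tuple(d["class_counts"]),
            class_label=d["class_label"],
            split_variable=d.get("split_variable"),
            split_threshold=d.get("split_threshold"),
        )
        node.children = [cls.from_dict(c) for c in d.get("children", [])]
        return node

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_text(self) -> str:
        """Indented human-readable rendering."""
        lines: list[str] = []

        def rec(node: DecisionTreeNode, prefix: str) -> None:
            if node.is_leaf:
                lines.append(f"{prefix}leaf: class={node.class_label} "
                             f"(n={node.n}, counts={node.class_counts})")
            else:
                lines.append(f"{prefix}{node.split_variable} <= {node.split_threshold:g} "
                             f"(n={node.n})")
                rec(node.children[0], prefix + "  ")
                lines.append(f"{prefix}{node.split_variable} > {node.split_threshold:g}")
                rec(node.children[1], prefix + "  ")

        rec(self, "")
        return "\n".join(lines)


def _entropy_from_counts(n1: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy (bits) for positive-count n1 of n; vectorized."""
    n = np.asarray(n, dtype=float)
    p = np.divide(n1, n, out=np.zeros_like(n, dtype=float), where=n > 0)
    h = np.zeros_like(p)
    for q in (p, 1.0 - p):
        mask = q > 0
        h[mask] -= q[mask] * np.log2(q[mask])
    return h


def best_split(X: pd.DataFrame, y: np.ndarray, min_leaf: int = 1):
    """Gain-ratio-maximizing split over all variables and midpoint thresholds.

    Returns ``(variable, threshold, gain_ratio)`` or ``None`` when no split
    has positive information gain or respects ``min_leaf``.  Ties (within
    1e-12) are broken by variable name order, then by the smaller threshold.
    """
    n = len(y)
    n1_total = int(y.sum())
    h_parent = _entropy_from_counts(np.array([n1_total]), np.array([n]))[0]
    best = None  # (neg_gain_ratio, variable, threshold)
    for var in sorted(X.columns):
        x = X[var].to_numpy(dtype=float)
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y[order]
        # candidate boundaries: between consecutive distinct values
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        if len(distinct) == 0:
            continue
        nl = distinct + 1                      # left sizes
        nr = n - nl
        valid = (nl >= min_leaf) & (nr >= min_leaf)
        if not valid.any():
            continue
        nl, nr, idx = nl[valid], nr[valid], distinct[valid]
        cum1 = np.cumsum(ys)
        n1l = cum1[idx]
        n1r = n1_total - n1l
        h_children = (nl * _entropy_from_counts(n1l, nl)
                      + nr * _entropy_from_counts(n1r, nr)) / n
        gain = h_parent - h_children
        pl = nl / n
        split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(split_info > _EPS, gain / split_info, -np.inf)
        ratio = np.where(gain > _EPS, ratio, -np.inf)
        thresholds = (xs[idx] + xs[idx + 1]) / 2.0
        k = int(np.argmax(ratio))
        # among ties within this variable, prefer the smaller threshold
        tied = np.nonzero(ratio >= ratio[k] - _EPS)[0]
        k = tied[int(np.argmin(thresholds[tied]))]
        if not np.isfinite(ratio[k]):
            continue
        cand = (float(ratio[k]), var, float(thresholds[k]))
        if best is None or cand[0] > best[0] + _EPS:
            best = cand
        # equal ratio: earlier variable name wins (already iterating sorted)
    if best is None:
        return None
    return best[1], best[2], best[0]


def build_c45_tree(X: pd.DataFrame, y, *, min_leaf: int = 25,
                   max_depth: int = 12) -> DecisionTreeNode:
    """Grow an unpruned gain-ratio tree on binary outcome ``y``.

    ``min_leaf`` applies to each child of a split; ``max_depth`` counts the
    root as level 1.  A single-class input yields a single leaf.
    """
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot build a tree on zero records")
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")

    def grow(idx: np.ndarray, depth: int) -> DecisionTreeNode:
        yy = y[idx]
        n1 = int(yy.sum())
        node = DecisionTreeNode(
            depth=depth, n=len(idx), class_counts=(len(idx) - n1, n1),
            class_label=int(n1 * 2 > len(idx)),
        )
        if n1 == 0 or n1 == len(idx) or depth >= max_depth or len(idx) < 2 * min_leaf:
            return node
        found = best_split(X.iloc[idx], yy, min_leaf=min_leaf)
        if found is None:
            return node
        var, thr, _ = found
        node.split_variable = var
        node.split_threshold = thr
        mask = X[var].to_numpy(dtype=float)[idx] <= thr
        node.children = [grow(idx[mask], depth + 1), grow(idx[~mask], depth + 1)]
        return node

    return grow(np.arange(len(y)), 1)


def cross_validated_trees(X: pd.DataFrame, y, *, folds: int = 10, seed: int = 0,
                          min_leaf: int = 25, max_depth: int = 12) -> list[DecisionTreeNode]:
    """One unpruned tree per CV training fold (k trees for k folds).

    Each tree is grown on the complement of one fold; fold membership is a
    seeded random partition.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} records for {folds}-fold CV")
    rng = np.random.default_rng(int(seed) % (2**31))
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds
    trees = []
    for f in range(folds):
        idx = np.nonzero(fold_of != f)[0]
        trees.append(build_c45_tree(X.iloc[idx].reset_index(drop=True), y[idx],
                                    min_leaf=min_leaf, max_depth=max_depth))
    return trees


def count_tree_frequencies(trees, max_level: int = 8) -> dict[str, int]:
    """Occurrences of each variable as an internal-node split within the
    first ``max_level`` levels, summed over all supplied trees."""
    counts: dict[str, int] = {}
    for tree in trees:
        for node in tree.walk():
            if not node.is_leaf and node.depth <= max_level:
                counts[node.split_variable] = counts.get(node.split_variable, 0) + 1
    return counts


#: Shipped fallback for the fasting-glucose cut-point (mmol/L).
DEFAULT_GLU_CUTOFF = 5.85


def extract_glycemia_cutoff(trees, *, variable: str = "glu", bin_width: float = 0.05,
                            max_level: int = 8) -> float | None:
    """Modal glucose split threshold across trees, binned to ``bin_width``.

    Thresholds from splits on ``variable`` within the first ``max_level``
    levels are rounded to the nearest bin; the most frequent bin wins, with
    ties broken toward the bin whose occurrences reach the shallowest level,
    then toward the smaller value.  Returns ``None`` when no such split
    exists (callers fall back to :data:`DEFAULT_GLU_CUTOFF`).
    """
    found: dict[float, list[int]] = {}
    for tree in trees:
        for node in tree.walk():
            if (not node.is_leaf and node.split_variable == variable
                    and node.depth <= max_level):
                binned = round(round(node.split_threshold / bin_width) * bin_width, 10)
                found.setdefault(binned, []).append(node.depth)
    if not found:
        return None
    return min(found, key=lambda b: (-len(found[b]), min(found[b]), b))
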