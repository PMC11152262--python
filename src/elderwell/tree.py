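"""Pre-pruned CART regression trees for the wellbeing indices.

Recursive binary splitting on squared-error reduction.  Numeric predictors
split on thresholds halfway between consecutive distinct values ("x <= t");
multi-level categorical predictors are split by the classical CART
mean-ordering device — order the levels by their mean outcome and treat the
ordering as ordinal — which is exactly optimal for a single squared-error
split.  Growth is pre-pruned, not post-pruned:

* a node with fewer than ``min_node`` observations (default 20) is never
  split further;
* a split is accepted only if its SSE reduction is at least
  ``min_gain_frac`` of the root SSE (default 1%), the complexity limit of
  the classical CART implementations.

Nodes are labelled in the field's usual way: mean outcome on top, share of
the root sample below (the root always reads 100%).  Ties between equal-gain
splits are broken by column order, then by the smaller threshold, so the
grown tree is a deterministic function of its input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass(frozen=True)
class SplitCandidate:
    """One candidate binary split and its squared-error reduction."""

    variable: str
    kind: str                      # "numeric" or "categorical"
    threshold: float | None = None
    categories: frozenset = frozenset()   # left-branch levels (categorical)
    gain: float = 0.0              # SSE reduction, outcome^2 units
    n_left: int = 0
    n_right: int = 0

    def goes_left(self, x) -> np.ndarray:
        x = np.asarray(x)
        if self.kind == "numeric":
            return x.astype(float) <= self.threshold
        return np.isin(x.astype(str), list(self.categories))

    def describe(self) -> str:
        if self.kind == "numeric":
            return f"{self.variable} <= {self.threshold:g}"
        cats = sorted(self.categories)
        if len(cats) == 1:
            return f"{self.variable}_{cats[0]}"
        return f"{self.variable} in {{{', '.join(cats)}}}"


@dataclass
class TreeNode:
    """A node of the fitted tree; a leaf when ``split`` is None."""

    mean: float
    n: int
    proportion: float              # share of the root sample, in [0, 1]
    split: Optional[SplitCandidate] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_dict(self) -> dict:
        d = {"mean": self.mean, "n": self.n, "proportion": self.proportion}
        if not self.is_leaf:
            d["rule"] = self.split.describe()
            d["gain"] = self.split.gain
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _best_numeric(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Best threshold and gain for one numeric predictor (cumulative sums)."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(ys)
    csum = np.cumsum(ys)
    csq = np.cumsum(ys**2)
    total_sse = csq[-1] - csum[-1] ** 2 / n
    # candidate cuts after position i (0-based), only between distinct values
    cuts = np.flatnonzero(np.diff(xs) > 0)
    if cuts.size == 0:
        return None
    nl = cuts + 1.0
    nr = n - nl
    sl, sr = csum[cuts], csum[-1] - csum[cuts]
    ql, qr = csq[cuts], csq[-1] - csq[cuts]
    gains = total_sse - (ql - sl**2 / nl) - (qr - sr**2 / nr)
    best = int(np.argmax(gains))          # argmax keeps the first (smaller t) on ties
    thr = 0.5 * (xs[cuts[best]] + xs[cuts[best] + 1])
    return thr, float(gains[best])


def best_split(X: pd.DataFrame, y) -> SplitCandidate | None:
    """Exhaustive best binary split of (X, y) by SSE reduction.

    Returns None when no split yields a positive gain (e.g. constant y).
    Numeric columns try every threshold between consecutive distinct
    values; categorical columns are ordered by within-level mean outcome
    and cut along that ordering.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        return None
    best: SplitCandidate | None = None
    for col in X.columns:
        series = X[col]
        numeric = pd.api.types.is_numeric_dtype(series) and not isinstance(
            series.dtype, pd.CategoricalDtype
        )
        if numeric:
            found = _best_numeric(series.to_numpy(dtype=float), y)
            if found is None:
                continue
            thr, gain = found
            mask = series.to_numpy(dtype=float) <= thr
            cand = SplitCandidate(
                variable=col, kind="numeric", threshold=thr, gain=gain,
                n_left=int(mask.sum()), n_right=int((~mask).sum()),
            )
        else:
            levels = series.astype(str).to_numpy()
            uniq = pd.unique(levels)
            if len(uniq) < 2:
                continue
            means = {u: y[levels == u].mean() for u in uniq}
            ordered = sorted(uniq, key=lambda u: (means[u], u))
            codes = np.array([ordered.index(v) for v in levels], dtype=float)
            found = _best_numeric(codes, y)
            if found is None:
                continue
            thr, gain = found
            left_levels = frozenset(ordered[: int(np.floor(thr)) + 1])
            mask = np.isin(levels, list(left_levels))
            cand = SplitCandidate(
                variable=col, kind="categorical", categories=left_levels, gain=gain,
                n_left=int(mask.sum()), n_right=int((~mask).sum()),
            )
        if cand.gain > 1e-12 and (best is None or cand.gain > best.gain + 1e-12):
            best = cand
    return best


def grow_tree(
    X: pd.DataFrame,
    y,
    min_node: int = 20,
    min_gain_frac: float = 0.01,
) -> TreeNode:
    """Grow a pre-pruned regression tree.

    A node with fewer than ``min_node`` rows is a leaf; a split is accepted
    only if its SSE reduction is at least ``min_gain_frac`` times the root
    SSE.  Rows with missing predictor or outcome values must be removed
    beforehand (see :class:`CARTRegressor`, which handles this).
    """
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    root_n = len(y)
    root_sse = _sse(y)
    min_gain = min_gain_frac * root_sse

    def build(idx: np.ndarray) -> TreeNode:
        yy = y[idx]
        node = TreeNode(mean=float(yy.mean()), n=len(idx), proportion=len(idx) / root_n)
        if len(idx) < min_node:
            return node
        cand = best_split(X.iloc[idx], yy)
        if cand is None or cand.gain < min_gain:
            return node
        mask = cand.goes_left(X.iloc[idx][cand.variable])
        node.split = cand
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    return build(np.arange(root_n))


def predict_tree(tree: TreeNode, X: pd.DataFrame) -> np.ndarray:
    out = np.empty(len(X))
    for i in range(len(X)):
        node = tree
        while not node.is_leaf:
            v = X.iloc[i][node.split.variable]
            node = node.left if node.split.goes_left([v])[0] else node.right
        out[i] = node.mean
    return out


def render_tree(tree: TreeNode) -> str:
    """Indented outline; each node prints ``mean / proportion%``.

    Means to 2 decimals, proportions to whole percents — the figure-label
    convention (root reads e.g. ``0.57 / 100%``).
    """

    def fmt(node: TreeNode) -> str:
        return f"{node.mean:.2f} / {round(node.proportion * 100):d}%"

    lines: list[str] = []

    def walk(node: TreeNode, prefix: str, tag: str) -> None:
        lines.append(f"{prefix}{tag}{fmt(node)}")
        if not node.is_leaf:
            rule = node.split.describe()
            indent = prefix + "  "
            walk(node.left, indent, f"[{rule}] ")
            walk(node.right, indent, f"[not {rule}] ")

    walk(tree, "", "")
    return "\n".join(lines)


class CARTRegressor(RegressorMixin, BaseEstimator):
    """Pre-pruned CART regression tree as an sklearn-style estimator.

    Parameters
    ----------
    min_node : int
        Minimum observations a node needs before a further split is
        considered (default 20).
    min_gain_frac : float
        Minimum SSE reduction for an accepted split, as a fraction of the
        root SSE (default 0.01).

    Attributes
    ----------
    tree_ : TreeNode — the fitted recursive structure.
    n_dropped_ : int — rows removed by the complete-case rule.
    feature_names_in_ : list of str
    """

    def __init__(self, min_node: int = 20, min_gain_frac: float = 0.01):
        self.min_node = min_node
        self.min_gain_frac = min_gain_frac

    def fit(self, X: pd.DataFrame, y) -> "CARTRegressor":
        X = pd.DataFrame(X).reset_index(drop=True)
        y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
        keep = X.notna().all(axis=1) & y.notna()
        self.n_dropped_ = int((~keep).sum())
        X, y = X.loc[keep].reset_index(drop=True), y.loc[keep]
        if len(X) == 0:
            raise ValueError("no complete cases to fit on")
        self.feature_names_in_ = list(X.columns)
        self.tree_ = grow_tree(X, y.to_numpy(), self.min_node, self.min_gain_frac)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "tree_"):
            raise RuntimeError("CARTRegressor instance is not fitted yet")
        return predict_tree(self.tree_, pd.DataFrame(X))

    def render(self) -> str:
        return render_tree(self.tree_)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.tree_.to_dict(), **kwargs)
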