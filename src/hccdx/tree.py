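"""Entropy / gain-ratio decision trees (ID3/C4.5 family) for binary labels.

The split criterion is information gain or gain ratio computed in bits.
Ratio-scaled features are split by binary thresholds placed at midpoints
between consecutive distinct sorted values; qualitative features split one
branch per observed category. Optional pessimistic error-based pruning
collapses subtrees whose upper-confidence training error is no better than
a leaf's. Ties are broken deterministically: lowest feature index, then
lowest threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaincinv, xlogy

_EPS = 1e-12


@dataclass
class TreeParams:
    criterion: str = "gain_ratio"        # "gain" for plain information gain
    min_leaf: int = 2
    max_depth: int | None = None
    prune: bool = True
    prune_confidence: float = 0.25

    def __post_init__(self):
        if self.criterion not in ("gain", "gain_ratio"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not (0 < self.prune_confidence < 1):
            raise ValueError("prune_confidence must be in (0,1)")


@dataclass
class TreeNode:
    counts: np.ndarray                    # class counts [n0, n1] at this node
    prediction: int
    feature: int | None = None
    threshold: float | None = None        # numeric: x <= threshold -> children[0]
    categories: list[float] | None = None  # qualitative: categories[k] -> children[k]
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children)

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children)


# ---------------------------------------------------------------- criteria

def _counts(y) -> np.ndarray:
    y = np.asarray(y)
    return np.array([int((y == 0).sum()), int((y == 1).sum())])


def _entropy_counts(c0, c1):
    """Shannon entropy in bits from class tallies (vectorized)."""
    n = c0 + c1
    n = np.where(n == 0, 1, n)
    p0, p1 = c0 / n, c1 / n
    return -(xlogy(p0, p0) + xlogy(p1, p1)) / np.log(2)


def entropy(labels) -> float:
    """Shannon entropy of a binary label vector, in bits; 0*log 0 = 0."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("entropy of an empty label vector is undefined")
    c = _counts(y)
    return float(_entropy_counts(c[0], c[1]))


def _branch_masks(column, split):
    """Boolean row masks for a split: a float threshold or 'categories'."""
    x = np.asarray(column, dtype=float)
    if split == "categories":
        return [x == v for v in np.unique(x)]
    thr = float(split)
    return [x <= thr, x > thr]


def residual_entropy(column, labels, split) -> float:
    """Sum_a p(a) * H(labels | branch a), empty branches dropped."""
    y = np.asarray(labels)
    masks = [m for m in _branch_masks(column, split) if m.any()]
    n = y.size
    return float(sum(m.sum() / n * entropy(y[m]) for m in masks))


def split_info(column, split) -> float:
    """-Sum_a p(a) log2 p(a) over non-empty branches (bits)."""
    x = np.asarray(column, dtype=float)
    sizes = np.array([m.sum() for m in _branch_masks(column, split) if m.any()])
    p = sizes / x.size
    return float(-(xlogy(p, p)).sum() / np.log(2))


def gain(column, labels, split) -> float:
    """Information gain; 0 when the split leaves a single non-empty branch."""
    masks = [m for m in _branch_masks(column, split) if m.any()]
    if len(masks) < 2:
        return 0.0
    return entropy(labels) - residual_entropy(column, labels, split)


def gain_ratio(column, labels, split) -> float:
    """Gain divided by split information; 0 when split information is 0."""
    si = split_info(column, split)
    if si <= _EPS:
        return 0.0
    return gain(column, labels, split) / si


# ---------------------------------------------------------- split search

def _best_threshold(x, y, min_leaf, criterion):
    """Best binary threshold for a numeric column, or None.

    Candidates are midpoints between consecutive distinct sorted values;
    scores are computed from cumulative class tallies in one vectorized
    pass. Returns (score, threshold)."""
    n = x.size
    # quicksort is fine: scores at value-change boundaries are invariant
    # to the order of tied rows, so the result is still deterministic
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    change = np.nonzero(xs[1:] != xs[:-1])[0] + 1      # left-block sizes
    if change.size == 0:
        return None
    left_sizes = change[(change >= min_leaf) & (n - change >= min_leaf)]
    if left_sizes.size == 0:
        return None
    cum1 = np.cumsum(ys)
    l1 = cum1[left_sizes - 1]
    l0 = left_sizes - l1
    t1 = cum1[-1]
    r1 = t1 - l1
    r0 = (n - left_sizes) - r1
    h_parent = _entropy_counts(n - t1, t1)
    res = (left_sizes / n) * _entropy_counts(l0, l1) \
        + ((n - left_sizes) / n) * _entropy_counts(r0, r1)
    g = h_parent - res
    if criterion == "gain_ratio":
        p = left_sizes / n
        si = -(xlogy(p, p) + xlogy(1 - p, 1 - p)) / np.log(2)
        score = np.where(si > _EPS, g / np.maximum(si, _EPS), 0.0)
    else:
        score = g
    best = int(np.argmax(score))           # first max -> lowest threshold
    i = left_sizes[best]
    thr = (xs[i - 1] + xs[i]) / 2.0
    return float(score[best]), thr


def _best_thresholds_all(X, y, min_leaf, criterion, cols):
    """Vectorized threshold search over the ratio columns ``cols``.

    One argsort/cumsum pass scores every candidate boundary of every
    column; ties resolve to the lowest feature index, then the lowest
    threshold (feature-major first-maximum). Returns (score, j, thr) or
    None when no admissible boundary exists."""
    n = X.shape[0]
    if n < 2:
        return None
    Xc = X[:, cols]
    order = np.argsort(Xc, axis=0)
    xs = np.take_along_axis(Xc, order, axis=0)
    ys = np.asarray(y)[order]
    cum1 = np.cumsum(ys, axis=0)
    left = np.arange(1, n, dtype=float)[:, None]          # left-block sizes
    l1 = cum1[:-1].astype(float)
    l0 = left - l1
    t1 = cum1[-1].astype(float)
    r1 = t1[None, :] - l1
    r0 = (n - left) - r1
    h_parent = _entropy_counts(n - t1, t1)                # per column
    res = (left / n) * _entropy_counts(l0, l1) \
        + ((n - left) / n) * _entropy_counts(r0, r1)
    g = h_parent[None, :] - res
    if criterion == "gain_ratio":
        p = left / n
        si = -(xlogy(p, p) + xlogy(1 - p, 1 - p)) / np.log(2)
        score = np.where(si > _EPS, g / np.maximum(si, _EPS), 0.0)
    else:
        score = g
    valid = (xs[1:] != xs[:-1]) \
        & (left >= min_leaf) & ((n - left) >= min_leaf)
    score = np.where(valid, score, -1.0)
    flat = score.T.ravel()                                # feature-major
    best = int(np.argmax(flat))
    if flat[best] <= _EPS:
        return None
    c, bi = divmod(best, n - 1)
    i = bi + 1
    thr = (xs[i - 1, c] + xs[i, c]) / 2.0
    return float(flat[best]), cols[c], float(thr)


def _best_categorical(x, y, min_leaf, criterion):
    """Score a one-branch-per-category split, or None if inadmissible."""
    cats = np.unique(x)
    if cats.size < 2:
        return None
    sizes = np.array([(x == v).sum() for v in cats])
    if (sizes < min_leaf).any():
        return None
    split = "categories"
    sc = gain_ratio(x, y, split) if criterion == "gain_ratio" else gain(x, y, split)
    return sc, cats


# ----------------------------------------------------------------- fitting

def fit_tree(X, y, params: TreeParams | None = None,
             feature_kinds: list[str] | None = None) -> TreeNode:
    """Grow a decision tree greedily by the configured criterion.

    ``feature_kinds`` marks each column ``"ratio"`` (binary threshold
    splits) or ``"qualitative"`` (multiway category splits); the default is
    all-ratio, which is the right choice after z-scoring. Growth stops on
    purity, ``min_leaf``, ``max_depth``, or when no split has positive
    criterion; leaves predict the majority label. Pessimistic error-based
    pruning runs bottom-up afterwards when ``params.prune`` is set.
    """
    params = params or TreeParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] == 0:
        raise ValueError("cannot fit a tree on zero rows")
    if np.isnan(X).any():
        raise ValueError("X contains NaN; impute before fitting")
    m = X.shape[1]
    kinds = feature_kinds or ["ratio"] * m
    if len(kinds) != m:
        raise ValueError("feature_kinds length mismatch")
    ratio_cols = [j for j in range(m) if kinds[j] != "qualitative"]
    qual_cols = [j for j in range(m) if kinds[j] == "qualitative"]

    def build(rows, depth):
        yy = y[rows]
        counts = _counts(yy)
        node = TreeNode(counts=counts, prediction=int(np.argmax(counts)))
        if counts[0] == 0 or counts[1] == 0:
            return node
        if params.max_depth is not None and depth >= params.max_depth:
            return node
        if rows.size < 2 * params.min_leaf:
            return node
        best_score, best = _EPS, None
        if ratio_cols:
            cand = _best_thresholds_all(X[rows], yy, params.min_leaf,
                                        params.criterion, ratio_cols)
            if cand is not None:
                best_score, best = cand[0], (cand[1], "threshold", cand[2])
        for j in qual_cols:
            cand = _best_categorical(X[rows, j], yy, params.min_leaf,
                                     params.criterion)
            if cand is not None and cand[0] > best_score:
                # qualitative splits win ties against higher-index ratio
                # splits only with a strictly better score
                best_score, best = cand[0], (j, "categories", cand[1])
        if best is None:
            return node
        j, mode, spec = best
        node.feature = j
        if mode == "threshold":
            node.threshold = float(spec)
            left = X[rows, j] <= node.threshold
            node.children = [build(rows[left], depth + 1),
                             build(rows[~left], depth + 1)]
        else:
            node.categories = [float(v) for v in spec]
            node.children = [build(rows[X[rows, j] == v], depth + 1)
                             for v in spec]
        return node

    root = build(np.arange(X.shape[0]), 0)
    if params.prune:
        _prune(root, params.prune_confidence)
    return root


def _pessimistic_errors(errors: int, n: int, cf: float) -> float:
    """n times the upper confidence bound on the leaf error rate (C4.5 U_CF)."""
    if n == 0:
        return 0.0
    if errors >= n:
        return float(n)
    return float(n * betaincinv(errors + 1, n - errors, 1.0 - cf))


def _prune(node: TreeNode, cf: float) -> float:
    """Collapse subtrees whose leaf estimate beats the children's sum."""
    n = node.n
    leaf_errors = n - int(node.counts.max())
    leaf_est = _pessimistic_errors(leaf_errors, n, cf)
    if node.is_leaf:
        return leaf_est
    subtree_est = sum(_prune(c, cf) for c in node.children)
    if leaf_est <= subtree_est:
        node.children = []
        node.feature = node.threshold = node.categories = None
        return leaf_est
    return subtree_est


# -------------------------------------------------------------- prediction

def predict_tree(tree: TreeNode, X) -> np.ndarray:
    """Deterministic descent; unseen categories route to the heaviest child."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    out = np.empty(X.shape[0], dtype=np.int64)

    def descend(node, rows):
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = node.prediction
            return
        xj = X[rows, node.feature]
        if node.threshold is not None:
            left = xj <= node.threshold
            descend(node.children[0], rows[left])
            descend(node.children[1], rows[~left])
        else:
            routed = np.zeros(rows.size, dtype=bool)
            for k, v in enumerate(node.categories):
                sel = xj == v
                routed |= sel
                descend(node.children[k], rows[sel])
            if not routed.all():
                heaviest = max(node.children, key=lambda c: c.n)
                descend(heaviest, rows[~routed])

    descend(tree, np.arange(X.shape[0]))
    return out


# ----------------------------------------------------------- serialization

def tree_to_dict(node: TreeNode) -> dict:
    d = {"counts": [int(c) for c in node.counts], "prediction": node.prediction}
    if not node.is_leaf:
        d["feature"] = node.feature
        if node.threshold is not None:
            d["threshold"] = node.threshold
        else:
            d["categories"] = node.categories
        d["children"] = [tree_to_dict(c) for c in node.children]
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(counts=np.array(d["counts"]), prediction=int(d["prediction"]))
    if "children" in d:
        node.feature = int(d["feature"])
        node.threshold = d.get("threshold")
        node.categories = d.get("categories")
        node.children = [tree_from_dict(c) for c in d["children"]]
    return node


def save_tree(node: TreeNode, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(node), fh, indent=1)


def load_tree(path) -> TreeNode:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))
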