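"""Bagged homogeneous decision-tree ensemble with a meta-classifier.

The training data is divided into Z bags — by default a stratified disjoint
partition, optionally bootstrap resamples — and one gain-ratio tree is
trained per bag. A meta-table is then built for every training row: the
selected features followed by the Z base-tree predictions. A second
gain-ratio tree trained on this table is the consensus function; unlike a
majority vote it can learn systematic mistakes of individual base trees
because it sees both their outputs and the raw features.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._rng import seed_stream
from .tree import TreeNode, TreeParams, fit_tree, predict_tree, save_tree, load_tree


@dataclass
class EnsembleConfig:
    n_bags: int = 4                     # Z
    bagging_mode: str = "partition"     # or "bootstrap"
    base_tree_params: TreeParams = field(default_factory=TreeParams)
    meta_tree_params: TreeParams = field(default_factory=TreeParams)
    oob_meta: bool = False              # use out-of-bag base predictions in the meta-table
    seed: int = 0

    def __post_init__(self):
        if self.n_bags < 1:
            raise ValueError("need at least one bag")
        if self.bagging_mode not in ("partition", "bootstrap"):
            raise ValueError(f"unknown bagging mode {self.bagging_mode!r}")


@dataclass
class EnsembleModel:
    base_trees: list[TreeNode]
    meta_tree: TreeNode
    bag_indices: list[np.ndarray]
    n_features: int
    single_class_bags: list[int] = field(default_factory=list)

    @property
    def n_bags(self) -> int:
        return len(self.base_trees)

    @property
    def meta_width(self) -> int:
        return self.n_features + self.n_bags


def make_bags(n: int, labels, Z: int, mode: str = "partition",
              rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Row-index sets for the Z bags.

    ``partition``: stratified disjoint split into Z near-equal parts
    covering every row exactly once (class members are shuffled and dealt
    round-robin). ``bootstrap``: Z independent samples of size n drawn with
    replacement.
    """
    if rng is None:
        rng = np.random.default_rng()
    labels = np.asarray(labels)
    if n < Z and mode == "partition":
        raise ValueError(f"cannot partition {n} rows into {Z} non-empty bags")
    if mode == "bootstrap":
        return [np.sort(rng.integers(n, size=n)) for _ in range(Z)]
    bags: list[list[int]] = [[] for _ in range(Z)]
    start = 0
    for cls in np.unique(labels):
        members = np.nonzero(labels == cls)[0]
        rng.shuffle(members)
        for i, row in enumerate(members):
            bags[(start + i) % Z].append(int(row))
        start += len(members)          # stagger classes across bags
    return [np.sort(np.array(b, dtype=np.int64)) for b in bags]


def _meta_table(X, base_preds):
    return np.column_stack([X, base_preds])


def fit_ensemble(X, y, config: EnsembleConfig | None = None,
                 rng: np.random.Generator | None = None) -> EnsembleModel:
    """Train Z base trees on Z bags plus the meta-classifier tree.

    ``X`` must already be restricted to the selected features and complete.
    The meta-table holds, per training row, the feature values followed by
    every base tree's prediction for that row; with ``oob_meta`` a tree's
    prediction for its own training rows is replaced by the majority vote
    of the other trees, trimming the in-bag optimism of the meta-table.
    A bag containing a single class is recorded (its tree degenerates to a
    leaf) but is not an error.
    """
    config = config or EnsembleConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = X.shape[0]
    if rng is None:
        rng = seed_stream(config.seed, "bags")
    bags = make_bags(n, y, config.n_bags, config.bagging_mode, rng)
    if any(len(b) == 0 for b in bags):
        raise ValueError("empty bag; reduce the number of bags")
    single_class = [z for z, b in enumerate(bags)
                    if np.unique(y[b]).size < 2]
    trees = [fit_tree(X[b], y[b], config.base_tree_params) for b in bags]
    base_preds = np.column_stack([predict_tree(t, X) for t in trees])
    if config.oob_meta and config.n_bags > 1:
        for z, b in enumerate(bags):
            others = np.delete(base_preds[b], z, axis=1)
            base_preds[b, z] = (others.mean(axis=1) >= 0.5).astype(np.int64)
    meta_tree = fit_tree(_meta_table(X, base_preds), y, config.meta_tree_params)
    return EnsembleModel(base_trees=trees, meta_tree=meta_tree,
                         bag_indices=bags, n_features=X.shape[1],
                         single_class_bags=single_class)


def predict_ensemble(model: EnsembleModel, X) -> np.ndarray:
    """Base predictions, appended to the features, descend the meta-tree."""
    X = np.asarray(X, float)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} feature columns, got {X.shape[1]}")
    base_preds = np.column_stack([predict_tree(t, X) for t in model.base_trees])
    return predict_tree(model.meta_tree, _meta_table(X, base_preds))


def base_majority_vote(model: EnsembleModel, X) -> np.ndarray:
    """Plain majority vote of the base trees (the consensus the meta-tree replaces)."""
    X = np.asarray(X, float)
    base_preds = np.column_stack([predict_tree(t, X) for t in model.base_trees])
    return (base_preds.mean(axis=1) >= 0.5).astype(np.int64)


def save_ensemble(model: EnsembleModel, directory, mask_bits=None,
                  manifest_extra: dict | None = None) -> None:
    os.makedirs(directory, exist_ok=True)
    for z, t in enumerate(model.base_trees):
        save_tree(t, os.path.join(directory, f"base_tree_{z}.json"))
    save_tree(model.meta_tree, os.path.join(directory, "meta_tree.json"))
    manifest = {
        "n_bags": model.n_bags,
        "n_features": model.n_features,
        "single_class_bags": model.single_class_bags,
        "bag_indices": [b.tolist() for b in model.bag_indices],
    }
    if mask_bits is not None:
        manifest["mask"] = [int(b) for b in mask_bits]
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_ensemble(directory) -> EnsembleModel:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    trees = [load_tree(os.path.join(directory, f"base_tree_{z}.json"))
             for z in range(manifest["n_bags"])]
    meta = load_tree(os.path.join(directory, "meta_tree.json"))
    bags = [np.array(b, dtype=np.int64) for b in manifest["bag_indices"]]
    return EnsembleModel(base_trees=trees, meta_tree=meta, bag_indices=bags,
                         n_features=manifest["n_features"],
                         single_class_bags=manifest.get("single_class_bags", []))
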