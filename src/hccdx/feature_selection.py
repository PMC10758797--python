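"""Binary wrapper feature selection driven by Harris Hawks Optimization.

Continuous hawk positions are mapped to feature-inclusion bits through the
V-shaped transfer function |(2/pi)*arctan((pi/2)*x)| with per-dimension
random thresholds. Subsets are scored by the cross-validated mean squared
error of a classifier restricted to the selected columns; for hard 0/1
predictions this MSE equals the misclassification rate, so minimizing it
maximizes accuracy. Fitness values are cached by bitstring so a mask is
never re-evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hho
from ._rng import seed_stream
from .ensemble import EnsembleConfig, fit_ensemble, predict_ensemble
from .io import TabularDataset
from .tree import TreeParams, fit_tree, predict_tree


@dataclass
class FeatureMask:
    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, [0, 1]).all():
            raise ValueError("mask bits must be 0/1")
        if self.fitness is not None and not (0.0 <= self.fitness <= 1.0):
            raise ValueError("MSE fitness must lie in [0,1]")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def selected_indices(self) -> np.ndarray:
        return np.nonzero(self.bits)[0]

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.bits.astype(bool)]


@dataclass
class FSConfig:
    """Wrapper-selection settings: the optimizer, the scorer, the encoding."""

    n_hawks: int = 30
    n_iter: int = 100
    bounds: tuple[float, float] = (-4.0, 4.0)
    fitness_mode: str = "ensemble"        # "ensemble" or "tree" (fast)
    cv_folds: int = 10
    tree_params: TreeParams = field(default_factory=TreeParams)
    ensemble_config: EnsembleConfig = field(default_factory=EnsembleConfig)
    shared_threshold: bool = False
    cache: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("internal CV needs at least 2 folds")
        if self.fitness_mode not in ("ensemble", "tree"):
            raise ValueError(f"unknown fitness mode {self.fitness_mode!r}")


def v_transfer(x):
    """V-shaped transfer: |(2/pi)*arctan((pi/2)*x)|, in [0, 1)."""
    return np.abs((2.0 / np.pi) * np.arctan((np.pi / 2.0) * np.asarray(x, float)))


def binarize(position, rng: np.random.Generator,
             shared_threshold: bool = False) -> FeatureMask:
    """Draw inclusion bits: bit_d = 1 iff v(position_d) >= r_d, r ~ U(0,1).

    With ``shared_threshold`` one threshold is drawn for all dimensions.
    An all-zero outcome is repaired by forcing one uniformly chosen bit, so
    the wrapper never scores an empty subset.
    """
    v = v_transfer(position)
    if shared_threshold:
        r = np.full(v.shape, rng.random())
    else:
        r = rng.random(v.shape)
    bits = (v >= r).astype(np.int8)
    if bits.sum() == 0:
        bits[rng.integers(bits.size)] = 1
    return FeatureMask(bits)


def _stratified_folds(y, k, rng):
    # local import would be circular the other way; sklearn does the folding
    from sklearn.model_selection import StratifiedKFold
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def subset_fitness(mask: FeatureMask, X, y, config: FSConfig,
                   rng: np.random.Generator | None = None) -> float:
    """Pooled out-of-fold MSE of the configured classifier on the subset.

    Predictions are hard labels, so the returned MSE is exactly
    1 - accuracy of the internal cross-validation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if mask.bits.size != X.shape[1]:
        raise ValueError(f"mask length {mask.bits.size} != {X.shape[1]} features")
    if rng is None:
        # folds and bag assignments depend only on the config seed, so a
        # mask's score is deterministic (cache-coherent) and invariant to
        # consistent column permutations
        rng = seed_stream(config.seed, "fitness")
    Xs = mask.apply(X)
    k = min(config.cv_folds, int(np.bincount(y, minlength=2).min()))
    k = max(k, 2)
    folds = _stratified_folds(y, k, rng)
    pred = np.empty_like(y)
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test, assume_unique=True)
        if config.fitness_mode == "tree":
            t = fit_tree(Xs[train], y[train], config.tree_params)
            pred[test] = predict_tree(t, Xs[test])
        else:
            cfg = replace(config.ensemble_config,
                          seed=int(rng.integers(2**31 - 1)))
            model = fit_ensemble(Xs[train], y[train], cfg)
            pred[test] = predict_ensemble(model, Xs[test])
    return float(np.mean((y - pred) ** 2))


@dataclass
class SelectionResult:
    mask: FeatureMask
    history: list[tuple[int, float, int]]    # (iteration, best MSE, n selected)
    n_evaluations: int
    n_classifier_fits: int

    def history_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,best_mse,n_selected\n")
            for t, f, n in self.history:
                fh.write(f"{t},{f},{n}\n")

    def mask_txt(self, path, feature_names=None) -> None:
        with open(path, "w") as fh:
            fh.write("".join(str(int(b)) for b in self.mask.bits) + "\n")
            if feature_names is not None:
                for i in self.mask.selected_indices():
                    fh.write(f"{feature_names[i]}\n")


def select_features(data, config: FSConfig, y=None) -> SelectionResult:
    """Run binary HHO wrapper selection; returns the best mask ever scored.

    ``data`` is a complete (imputed, normalized) :class:`TabularDataset`
    or a plain feature matrix with ``y`` given separately.
    """
    if isinstance(data, TabularDataset):
        if not data.is_complete():
            raise ValueError("feature selection requires a preprocessed "
                             "(complete) dataset")
        X, y = data.values, data.labels
    else:
        X = np.asarray(data, float)
        if y is None:
            raise ValueError("labels required when passing a raw matrix")
    m = X.shape[1]
    lb, ub = config.bounds
    params = hho.HHOParams(n_hawks=config.n_hawks, n_iter=config.n_iter,
                           lb=lb, ub=ub, dim=m)
    hho_rng = seed_stream(config.seed, "hho")
    bin_rng = seed_stream(config.seed, "binarize")

    cache: dict[bytes, float] = {}
    fits = [0]
    best = {"mask": None, "fitness": np.inf}

    def objective(position):
        mask = binarize(position, bin_rng, config.shared_threshold)
        key = mask.bits.tobytes()
        if config.cache and key in cache:
            mse = cache[key]
        else:
            mse = subset_fitness(mask, X, y, config)
            fits[0] += 1
            if config.cache:
                cache[key] = mse
        if mse < best["fitness"]:
            best["fitness"] = mse
            best["mask"] = mask.bits.copy()
        return mse

    history: list[tuple[int, float, int]] = []

    def log(t, state):
        bits = best["mask"]
        history.append((t, float(best["fitness"]), int(bits.sum())))

    result = hho.optimize(objective, params, rng=hho_rng, callback=log)
    mask = FeatureMask(best["mask"], fitness=float(best["fitness"]))
    return SelectionResult(mask=mask, history=history,
                           n_evaluations=result.n_evals,
                           n_classifier_fits=fits[0])
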