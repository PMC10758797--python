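"""Missing-value imputation and z-score normalization.

Six imputation strategies for clinical tables: per-feature mean, median,
highest (maximum), constant zero, constant one, and an iterative
round-robin scheme that regresses each incomplete feature on all others by
ordinary least squares and re-predicts its missing cells until the imputed
values stop moving. Imputation always precedes normalization; the
normalizer refuses tables that still contain masked cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import TabularDataset

IMPUTE_METHODS = ("mean", "median", "highest", "zero", "ones", "iterative")


@dataclass
class ImputerModel:
    method: str
    fill_values: np.ndarray | None = None        # per-feature initial fills
    coefficients: dict[int, np.ndarray] = field(default_factory=dict)
    intercepts: dict[int, float] = field(default_factory=dict)
    rounds_used: int = 0
    max_rounds: int = 10
    tol: float = 1e-3
    n_features: int = 0
    change_history: list[float] = field(default_factory=list)  # iterative: sum of squared cell changes per round


def _column_fill(values, mask, method, names):
    n, m = values.shape
    fills = np.empty(m)
    for j in range(m):
        obs = values[~mask[:, j], j]
        if obs.size == 0:
            raise ValueError(f"feature {names[j]!r} has no observed values; "
                             f"cannot impute with method {method!r}")
        if method in ("mean", "iterative"):
            fills[j] = obs.mean()
        elif method == "median":
            fills[j] = np.median(obs)
        elif method == "highest":
            fills[j] = obs.max()
    return fills


def fit_imputer(ds: TabularDataset, method: str = "median",
                max_rounds: int = 10, tol: float = 1e-3) -> ImputerModel:
    """Learn per-feature fill values (and, for ``iterative``, regressions).

    The iterative method initializes missing cells at the feature means and
    then, in round-robin order over incomplete features, fits an ordinary
    least-squares regression of that feature on all others over its observed
    rows (using current imputations for the predictors) and re-predicts its
    missing cells. Rounds stop when the largest absolute change of any
    imputed cell drops below ``tol`` or after ``max_rounds`` rounds; the
    final round's coefficients are stored so the model can fill new tables.
    """
    if method not in IMPUTE_METHODS:
        raise ValueError(f"unknown imputation method {method!r}")
    model = ImputerModel(method=method, max_rounds=max_rounds, tol=tol,
                         n_features=ds.n_features)
    if method == "zero":
        model.fill_values = np.zeros(ds.n_features)
        return model
    if method == "ones":
        model.fill_values = np.ones(ds.n_features)
        return model
    model.fill_values = _column_fill(ds.values, ds.missing, method,
                                     ds.feature_names)
    if method != "iterative":
        return model

    X = ds.values.copy()
    mask = ds.missing
    for j in range(ds.n_features):
        X[mask[:, j], j] = model.fill_values[j]
    incomplete = [j for j in range(ds.n_features) if mask[:, j].any()]
    rounds = 0
    for _ in range(max_rounds):
        max_change = 0.0
        sq_change = 0.0
        for j in incomplete:
            others = [k for k in range(ds.n_features) if k != j]
            obs = ~mask[:, j]
            A = np.column_stack([X[obs][:, others], np.ones(obs.sum())])
            beta, *_ = np.linalg.lstsq(A, X[obs, j], rcond=None)
            model.coefficients[j] = beta[:-1]
            model.intercepts[j] = float(beta[-1])
            miss = mask[:, j]
            pred = X[miss][:, others] @ beta[:-1] + beta[-1]
            delta = pred - X[miss, j]
            max_change = max(max_change, float(np.abs(delta).max(initial=0.0)))
            sq_change += float((delta ** 2).sum())
            X[miss, j] = pred
        rounds += 1
        model.change_history.append(sq_change)
        if max_change < tol:
            break
    model.rounds_used = rounds
    return model


def _round_qualitative(values, ds: TabularDataset):
    """Round filled cells of dichotomous/ordinal features half-up in range."""
    if ds.schema is None:
        return values
    for j, spec in enumerate(ds.schema.features):
        if spec.qualitative:
            filled = ds.missing[:, j]
            v = np.floor(values[filled, j] + 0.5)          # half-up
            values[filled, j] = np.clip(v, spec.low, spec.high)
    return values


def apply_imputer(model: ImputerModel, ds: TabularDataset) -> TabularDataset:
    """Fill every masked cell; observed cells are returned unchanged.

    Qualitative features (when the dataset carries a schema) are rounded
    half-up to the nearest admissible integer after filling, so category
    codes stay categorical.
    """
    if model.n_features and ds.n_features != model.n_features:
        raise ValueError(f"dataset has {ds.n_features} features, model expects {model.n_features}")
    X = ds.values.copy()
    mask = ds.missing
    for j in range(ds.n_features):
        X[mask[:, j], j] = model.fill_values[j]
    if model.method == "iterative" and model.coefficients:
        incomplete = [j for j in sorted(model.coefficients) if mask[:, j].any()]
        for _ in range(model.max_rounds):
            max_change = 0.0
            for j in incomplete:
                others = [k for k in range(ds.n_features) if k != j]
                miss = mask[:, j]
                pred = X[miss][:, others] @ model.coefficients[j] + model.intercepts[j]
                max_change = max(max_change, float(np.abs(pred - X[miss, j]).max(initial=0.0)))
                X[miss, j] = pred
            if max_change < model.tol:
                break
    X = _round_qualitative(X, ds)
    empty = np.zeros_like(mask)
    return TabularDataset(X, empty, ds.labels.copy(), list(ds.feature_names),
                          ds.schema)


@dataclass
class NormalizerModel:
    mean: np.ndarray
    sd: np.ndarray          # zero for constant columns; such columns map to 0
    sd_convention: str = "population"


def fit_normalizer(ds: TabularDataset, sd_convention: str = "population") -> NormalizerModel:
    """Per-feature mean and SD for z-scoring. Requires a complete table."""
    if ds.missing.any():
        raise ValueError("normalizer requires an imputed (complete) dataset; "
                         "apply an imputer first")
    if sd_convention not in ("population", "sample"):
        raise ValueError(f"unknown sd convention {sd_convention!r}")
    ddof = 0 if sd_convention == "population" else 1
    mu = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=ddof)
    return NormalizerModel(mu, sd, sd_convention)


def apply_normalizer(model: NormalizerModel, ds: TabularDataset) -> TabularDataset:
    """z = (x - mu) / sigma per feature; zero-variance features map to 0."""
    if ds.missing.any():
        raise ValueError("normalizer requires an imputed (complete) dataset")
    sd = np.where(model.sd > 0, model.sd, 1.0)
    Z = (ds.values - model.mean) / sd
    Z[:, model.sd == 0] = 0.0
    return TabularDataset(Z, np.zeros_like(ds.missing), ds.labels.copy(),
                          list(ds.feature_names), ds.schema)


def preprocess(ds: TabularDataset, method: str = "median",
               normalize: bool = True, max_rounds: int = 10,
               tol: float = 1e-3, sd_convention: str = "population") -> TabularDataset:
    """Impute then (optionally) z-score: the standard pipeline order."""
    imp = fit_imputer(ds, method, max_rounds=max_rounds, tol=tol)
    out = apply_imputer(imp, ds)
    if normalize:
        norm = fit_normalizer(out, sd_convention)
        out = apply_normalizer(norm, out)
    return out
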