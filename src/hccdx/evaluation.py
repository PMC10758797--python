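"""Confusion-matrix metrics, stratified CV, and the experiment runner.

Accuracy, precision, recall and F1 are computed from TP/FP/TN/FN tallies
with the positive class = label 1 ("lives"). The full-pipeline runner
repeats shuffled stratified k-fold cross-validation (default k=10, 20
runs) around preprocessing, optional wrapper feature selection, and the
bagged meta-ensemble, reporting each metric as mean (SD) over runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._rng import seed_stream
from .ensemble import EnsembleConfig, fit_ensemble, predict_ensemble
from .io import TabularDataset
from .preprocess import preprocess as _preprocess
from .preprocess import fit_imputer, apply_imputer, fit_normalizer, apply_normalizer

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, positive_label: int = 1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = y_true == positive_label
    hit = y_true == y_pred
    return ConfusionCounts(
        tp=int((pos & hit).sum()), fp=int((~pos & ~hit).sum()),
        tn=int((~pos & hit).sum()), fn=int((pos & ~hit).sum()))


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()   # metrics whose denominator was zero

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall, F1 from tallies; 0/0 ratios become 0."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    undefined = []
    acc = (counts.tp + counts.tn) / counts.total
    prec = rec = f1 = 0.0
    if counts.tp + counts.fp > 0:
        prec = counts.tp / (counts.tp + counts.fp)
    else:
        undefined.append("precision")
    if counts.tp + counts.fn > 0:
        rec = counts.tp / (counts.tp + counts.fn)
    else:
        undefined.append("recall")
    if prec + rec > 0:
        f1 = 2 * prec * rec / (prec + rec)
    else:
        undefined.append("f1")
    return Metrics(acc, prec, rec, f1, tuple(undefined))


def stratified_kfold(labels, k: int, rng: np.random.Generator | None = None):
    """k disjoint, covering folds with per-fold class proportions within
    one sample of the global proportions. Returns test-index arrays."""
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if rng is None:
        rng = np.random.default_rng()
    state = int(rng.integers(2**31 - 1))
    if np.bincount(labels, minlength=2).min() < k:
        warnings.warn("a class has fewer members than folds; some folds "
                      "will lack that class", stacklevel=2)
        from sklearn.model_selection import KFold
        kf = KFold(n_splits=k, shuffle=True, random_state=state)
        return [test for _, test in kf.split(np.zeros(n))]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
    return [test for _, test in skf.split(np.zeros(n), labels)]


@dataclass
class EvalReport:
    per_run: list[dict]                  # run-level averaged metrics
    per_fold: list[list[dict]]           # fold-level metrics per run
    mean: dict[str, float]
    sd: dict[str, float]                 # population SD of per-run means
    n_selected: list[int]
    config: dict
    seed: int

    def to_text(self) -> str:
        lines = []
        for name in METRIC_NAMES:
            lines.append(f"{name:<10} {self.mean[name]:.3f} ({self.sd[name]:.3f})")
        if self.n_selected:
            lines.append(f"{'features':<10} " +
                         "/".join(str(n) for n in sorted(set(self.n_selected))))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("run," + ",".join(METRIC_NAMES) + ",n_selected\n")
            for r, row in enumerate(self.per_run):
                nsel = self.n_selected[r] if self.n_selected else ""
                fh.write(f"{r}," + ",".join(f"{row[m]}" for m in METRIC_NAMES)
                         + f",{nsel}\n")


def _aggregate(per_run):
    mean = {m: float(np.mean([r[m] for r in per_run])) for m in METRIC_NAMES}
    sd = {m: float(np.std([r[m] for r in per_run])) for m in METRIC_NAMES}
    return mean, sd


def run_experiment(ds: TabularDataset,
                   impute_method: str = "median",
                   normalize: bool = True,
                   fs_config=None,
                   ensemble_config: EnsembleConfig | None = None,
                   k: int = 10,
                   runs: int = 20,
                   seed: int = 0,
                   leakage_mode: str = "pooled") -> EvalReport:
    """Repeated stratified k-fold evaluation of the full pipeline.

    ``fs_config=None`` disables feature selection. ``leakage_mode``
    "pooled" preprocesses (and selects features) once on the full table
    before cross-validation; "strict" refits the imputer and normalizer on
    each training split and reruns selection per fold, the leakage-safe
    alternative.
    """
    from .feature_selection import FSConfig, FeatureMask, select_features

    ensemble_config = ensemble_config or EnsembleConfig()
    if leakage_mode not in ("pooled", "strict"):
        raise ValueError(f"unknown leakage mode {leakage_mode!r}")

    per_run, per_fold_all, n_selected = [], [], []
    for r in range(runs):
        run_seed = int(seed_stream(seed, "run", str(r)).integers(2**31 - 1))
        fold_rng = seed_stream(run_seed, "folds")
        if leakage_mode == "pooled":
            pre = _preprocess(ds, impute_method, normalize)
            if fs_config is not None:
                from dataclasses import replace as _replace
                sel = select_features(pre, _replace(fs_config, seed=run_seed))
                mask = sel.mask
            else:
                mask = FeatureMask(np.ones(pre.n_features, dtype=np.int8))
            Xall, yall = mask.apply(pre.values), pre.labels
            folds = stratified_kfold(yall, k, fold_rng)
            fold_metrics = []
            for f, test in enumerate(folds):
                train = np.setdiff1d(np.arange(len(yall)), test, assume_unique=True)
                from dataclasses import replace as _replace
                cfg = _replace(ensemble_config,
                               seed=int(seed_stream(run_seed, "bags", str(f))
                                        .integers(2**31 - 1)))
                model = fit_ensemble(Xall[train], yall[train], cfg)
                pred = predict_ensemble(model, Xall[test])
                fold_metrics.append(metrics(confusion(yall[test], pred)).as_dict())
        else:
            folds = stratified_kfold(ds.labels, k, fold_rng)
            fold_metrics = []
            mask = None
            for f, test in enumerate(folds):
                train = np.setdiff1d(np.arange(ds.n_samples), test, assume_unique=True)
                sub_train = TabularDataset(ds.values[train], ds.missing[train],
                                           ds.labels[train], list(ds.feature_names),
                                           ds.schema)
                sub_test = TabularDataset(ds.values[test], ds.missing[test],
                                          ds.labels[test], list(ds.feature_names),
                                          ds.schema)
                imp = fit_imputer(sub_train, impute_method)
                tr = apply_imputer(imp, sub_train)
                te = apply_imputer(imp, sub_test)
                if normalize:
                    norm = fit_normalizer(tr)
                    tr, te = apply_normalizer(norm, tr), apply_normalizer(norm, te)
                if fs_config is not None:
                    from dataclasses import replace as _replace
                    fold_seed = int(seed_stream(run_seed, "fs", str(f)).integers(2**31 - 1))
                    sel = select_features(tr, _replace(fs_config, seed=fold_seed))
                    mask = sel.mask
                else:
                    mask = FeatureMask(np.ones(tr.n_features, dtype=np.int8))
                from dataclasses import replace as _replace
                cfg = _replace(ensemble_config,
                               seed=int(seed_stream(run_seed, "bags", str(f))
                                        .integers(2**31 - 1)))
                model = fit_ensemble(mask.apply(tr.values), tr.labels, cfg)
                pred = predict_ensemble(model, mask.apply(te.values))
                fold_metrics.append(metrics(confusion(te.labels, pred)).as_dict())
        run_avg = {m: float(np.mean([fm[m] for fm in fold_metrics]))
                   for m in METRIC_NAMES}
        per_run.append(run_avg)
        per_fold_all.append(fold_metrics)
        n_selected.append(int(mask.n_selected))

    mean, sd = _aggregate(per_run)
    config_snapshot = {
        "impute_method": impute_method, "normalize": normalize,
        "feature_selection": fs_config is not None,
        "n_bags": ensemble_config.n_bags,
        "bagging_mode": ensemble_config.bagging_mode,
        "k": k, "runs": runs, "leakage_mode": leakage_mode,
    }
    return EvalReport(per_run=per_run, per_fold=per_fold_all, mean=mean,
                      sd=sd, n_selected=n_selected, config=config_snapshot,
                      seed=seed)
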