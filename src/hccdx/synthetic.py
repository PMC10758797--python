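"""Synthetic clinical tables that emulate a declarative schema.

The generator reproduces each feature's marginal (Bernoulli for
dichotomous codes, discretized truncated normals for ordinal grades,
truncated normals for ratio measurements), plants a discriminative signal
in a chosen subset of features by class-conditional mean shifts, and can
inject missing-completely-at-random cells at the schema's per-feature
rates. Every other module is therefore testable without the original
clinical data file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from ._rng import seed_stream
from .io import TabularDataset
from .schema import DatasetSchema, builtin_hcc_schema


@dataclass
class SignalSpec:
    """Which features carry class signal and how strongly.

    ``effects[i]`` is the standardized mean separation between classes for
    informative feature ``informative[i]`` (a log-odds shift for
    dichotomous features). Shifts are weighted by class prevalence so
    marginal moments stay at their schema targets.
    """

    informative: list[int] = field(default_factory=list)
    effects: list[float] = field(default_factory=list)
    prevalence: float = 0.5
    label_noise: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0,1)")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label noise must be in [0, 0.5)")
        if len(self.effects) not in (0, len(self.informative)):
            raise ValueError("one effect size per informative feature")
        if not self.effects and self.informative:
            self.effects = [1.0] * len(self.informative)


def _truncated_normal(mean, sd, low, high, size, rng, max_tries=100):
    """Rejection-sample N(mean, sd) into [low, high]; clamp stragglers."""
    if sd == 0:
        return np.full(size, np.clip(mean, low, high))
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    for _ in range(max_tries):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return np.clip(out, low, high)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate(schema: DatasetSchema, n: int, signal: SignalSpec | None = None,
             seed: int = 0) -> TabularDataset:
    """Draw an n-row table matching the schema's marginals, with labels.

    Labels are Bernoulli at ``signal.prevalence``. Informative ratio or
    ordinal features get class-conditional means ``mean + e*sd*(1-p)`` for
    the positive class and ``mean - e*sd*p`` for the negative class (so the
    marginal mean stays at ``mean``); informative dichotomous features get
    the analogous prevalence-weighted log-odds shift. Non-informative
    features are independent of the label. Labels are then flipped at the
    ``label_noise`` rate.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    signal = signal or SignalSpec()
    m = len(schema)
    for idx in signal.informative:
        if not (0 <= idx < m):
            raise ValueError(f"informative feature index {idx} out of range")
    rng = seed_stream(seed, "synth")
    p = signal.prevalence
    y = (rng.random(n) < p).astype(np.int64)
    effects = dict(zip(signal.informative, signal.effects))

    X = np.empty((n, m))
    for j, spec in enumerate(schema.features):
        e = effects.get(j, 0.0)
        if spec.kind == "dichotomous":
            base = np.clip(spec.mean, 1e-6, 1 - 1e-6)
            logit = np.log(base / (1 - base))
            prob = np.where(y == 1, _sigmoid(logit + e * (1 - p)),
                            _sigmoid(logit - e * p))
            X[:, j] = (rng.random(n) < prob).astype(float)
        else:
            shift = np.where(y == 1, e * spec.sd * (1 - p), -e * spec.sd * p)
            col = np.empty(n)
            for cls_shift in np.unique(shift):
                sel = shift == cls_shift
                col[sel] = _truncated_normal(spec.mean + cls_shift, spec.sd,
                                             spec.low, spec.high,
                                             int(sel.sum()), rng)
            if spec.kind == "ordinal":
                col = np.clip(np.floor(col + 0.5), spec.low, spec.high)
            X[:, j] = col

    if signal.label_noise > 0:
        flip = rng.random(n) < signal.label_noise
        y = np.where(flip, 1 - y, y)

    return TabularDataset(X, np.zeros((n, m), dtype=bool), y,
                          schema.names, schema)


def inject_missingness(ds: TabularDataset, rates=None, seed: int = 0) -> TabularDataset:
    """Mask cells independently (MCAR) at per-feature rates.

    ``rates`` may be a scalar, a per-feature sequence, or None to use the
    dataset schema's missingness rates. Labels are never masked.
    """
    if rates is None:
        if ds.schema is None:
            raise ValueError("no rates given and dataset has no schema")
        rates = [f.missing_rate for f in ds.schema.features]
    rates = np.broadcast_to(np.asarray(rates, float), (ds.n_features,))
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("missingness rates must lie in [0,1]")
    rng = seed_stream(seed, "missingness")
    mask = rng.random(ds.values.shape) < rates[None, :]
    return TabularDataset(ds.values, ds.missing | mask, ds.labels,
                          list(ds.feature_names), ds.schema)


def hcc_like(n: int = 165, informative: list[int] | None = None,
             effects: list[float] | None = None, seed: int = 0,
             with_missingness: bool = True) -> TabularDataset:
    """Convenience: a table with the built-in HCC schema's marginals,
    class balance 102/165 positive, and (optionally) its missingness."""
    schema = builtin_hcc_schema()
    signal = SignalSpec(informative=informative or [],
                        effects=effects or [],
                        prevalence=102 / 165)
    ds = generate(schema, n, signal, seed=seed)
    if with_missingness:
        ds = inject_missingness(ds, seed=seed)
    return ds


def planted_benchmark(n: int = 300, m: int = 30, k_informative: int = 5,
                      effect: float = 1.0, prevalence: float = 0.5,
                      seed: int = 0) -> TabularDataset:
    """Feature-selection benchmark: m standard-normal ratio features of
    which the first ``k_informative`` separate the classes by ``effect``
    standard deviations. Complete (no missingness) by construction."""
    from .schema import FeatureSpec
    feats = [FeatureSpec(name=f"x{j}", kind="ratio", low=-8.0, high=8.0,
                         mean=0.0, sd=1.0) for j in range(m)]
    schema = DatasetSchema(features=feats)
    signal = SignalSpec(informative=list(range(k_informative)),
                        effects=[effect] * k_informative,
                        prevalence=prevalence)
    return generate(schema, n, signal, seed=seed)


def mini_hcc_path() -> str:
    """Path of the bundled synthetic mini-HCC CSV fixture (40 x 12).

    The file is the output of ``mini_hcc()`` with its default seed,
    written by ``save_table``; it exists so loader-facing examples and
    quick starts have a file to point at without generating one.
    """
    return os.path.join(os.path.dirname(__file__), "data", "mini_hcc.csv")


def mini_hcc(n: int = 40, seed: int = 7) -> TabularDataset:
    """A small fixture table: the first 12 HCC features, mild signal."""
    schema = builtin_hcc_schema()
    sub = DatasetSchema(features=schema.features[:12],
                        label_name=schema.label_name,
                        positive_label_meaning=schema.positive_label_meaning)
    signal = SignalSpec(informative=[0, 3], effects=[1.0, 1.0],
                        prevalence=102 / 165)
    ds = generate(sub, n, signal, seed=seed)
    return inject_missingness(ds, seed=seed)
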