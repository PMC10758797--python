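"""Run configuration: documented defaults, YAML files, strict key checking.

Configuration is nested dot-keyed (``impute.method``, ``fs.n_iter`` ...).
Precedence is CLI override > file > defaults; unknown keys are rejected so
typos fail loudly instead of silently running the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .ensemble import EnsembleConfig
from .feature_selection import FSConfig
from .tree import TreeParams

# every leaf key and its default; the single source of truth
DEFAULTS: dict = {
    "data": {
        "path": None,                  # CSV path; None -> synthesize
        "missing_markers": ["?", "", "NA"],
        "label_column": "Class",
    },
    "synth": {
        "n": 165,
        "informative": [],
        "effects": [],
        "prevalence": 102 / 165,
        "label_noise": 0.0,
        "with_missingness": True,
        "n_features": None,            # None -> full 49-feature HCC schema
    },
    "impute": {"method": "median", "max_rounds": 10, "tol": 1e-3},
    "normalize": {"enabled": True, "sd_convention": "population"},
    "fs": {
        "enabled": True,
        "n_hawks": 30,
        "n_iter": 100,
        "bounds": [-4.0, 4.0],
        "fitness_mode": "ensemble",
        "cv_folds": 10,
        "shared_threshold": False,
    },
    "ensemble": {"n_bags": 4, "bagging_mode": "partition", "oob_meta": False},
    "tree": {
        "criterion": "gain_ratio",
        "min_leaf": 2,
        "max_depth": None,
        "prune": True,
        "prune_confidence": 0.25,
    },
    "eval": {"k": 10, "runs": 20, "leakage_mode": "pooled"},
    "seed": 0,
    "out_dir": "hccdx_out",
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    settings: dict = field(default_factory=lambda: _deep_copy(DEFAULTS))

    def __getitem__(self, dotted: str):
        node = self.settings
        for part in dotted.split("."):
            node = node[part]
        return node

    def set(self, dotted: str, value) -> None:
        parts = dotted.split(".")
        node = self.settings
        for part in parts[:-1]:
            if part not in node:
                raise KeyError(f"unknown configuration section {part!r}")
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown configuration key {dotted!r}")
        node[parts[-1]] = value

    def tree_params(self) -> TreeParams:
        t = self["tree"]
        return TreeParams(criterion=t["criterion"], min_leaf=t["min_leaf"],
                          max_depth=t["max_depth"], prune=t["prune"],
                          prune_confidence=t["prune_confidence"])

    def ensemble_config(self, seed: int = 0) -> EnsembleConfig:
        e = self["ensemble"]
        return EnsembleConfig(n_bags=e["n_bags"], bagging_mode=e["bagging_mode"],
                              base_tree_params=self.tree_params(),
                              meta_tree_params=self.tree_params(),
                              oob_meta=e["oob_meta"], seed=seed)

    def fs_config(self, seed: int = 0) -> FSConfig:
        f = self["fs"]
        return FSConfig(n_hawks=f["n_hawks"], n_iter=f["n_iter"],
                        bounds=tuple(f["bounds"]),
                        fitness_mode=f["fitness_mode"], cv_folds=f["cv_folds"],
                        tree_params=self.tree_params(),
                        ensemble_config=self.ensemble_config(seed),
                        shared_threshold=f["shared_threshold"], seed=seed)

    def snapshot(self) -> dict:
        return _deep_copy(self.settings)


def _deep_copy(node):
    if isinstance(node, dict):
        return {k: _deep_copy(v) for k, v in node.items()}
    if isinstance(node, list):
        return list(node)
    return node


def _merge(base: dict, override: dict, prefix: str = "") -> None:
    for key, value in override.items():
        dotted = f"{prefix}{key}"
        if key not in base:
            raise KeyError(f"unknown configuration key {dotted!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"{dotted!r} must be a mapping")
            _merge(base[key], value, dotted + ".")
        else:
            base[key] = value


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Defaults, then the YAML file, then dotted-key overrides."""
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        _merge(cfg.settings, doc)
    for dotted, value in (overrides or {}).items():
        cfg.set(dotted, value)
    return cfg
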