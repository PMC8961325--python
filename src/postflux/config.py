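"""Run configuration: defaults, YAML round-trip, and config hashing.

A run configuration is a plain nested mapping so it round-trips
losslessly through YAML; every pipeline run writes its resolved
configuration and a short hash beside its outputs so results can be
traced to the exact settings that produced them.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "design": {
        "n_subjects": 11,
        "n_replicates": 3,
        "tracer_fraction": 0.02,
        "carbohydrate_g": 50.0,
    },
    "noise": {
        "replicate_cv": 0.10,
        "subject_sd": 0.15,
        "baseline_sd": 0.02,
    },
    "schedule": {"s_pa": 1.0, "s_a": 1.0},
    "preprocess": {
        "sigma_floor_abs": 1e-6,
        "sigma_floor_rel": 0.0,
        "subject_agg": "mean",
        "iqr_factor": 1.5,
        "min_group_size": 4,
    },
    "fit": {
        "n_restarts": 50,
        "maxiter": 150,
        "pop_size": 60,
        "log_bounds": [-5.0, 1.0],
        "ratio_bounds": [0.1, 10.0],
        "deep_polish": True,
    },
    "split": {
        "candidates": [75.0, 90.0, 105.0, 120.0, 150.0],
        "whole_window": [0.0, 360.0],
    },
    "mcmc": {"n": 10000, "burn_frac": 0.5, "min_burn_gens": 1000, "thin": 8},
    "flux": {"late_uses_s_pa": True, "level": 0.90},
    # nominal total plasma pools (uM) for the contribution report
    "total_pools": {
        "glucose": 6000.0,
        "pyruvate": 60.0,
        "lactate": 2000.0,
        "alanine": 400.0,
        "citrate": 120.0,
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run."""

    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        cfg = cls()
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            _deep_update(cfg.values, user)
        return cfg

    def __getitem__(self, key: str):
        return self.values[key]

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)

    def hash(self) -> str:
        canon = yaml.safe_dump(self.values, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
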