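"""YAML-backed run configuration for the command-line pipeline.

One configuration file drives every command.  Sections mirror the library
objects one-to-one (phantom spec, network grid, network, schedule, loss,
optimizer, experiment settings); CLI flags override individual keys.  Two
named profiles exist:

* ``paper`` — the full-scale configuration: 128^3 grid, 5 levels, N=1000,
  M=2000, 15000 iterations;
* ``desk`` — a scaled-down configuration that runs the complete pipeline on
  one CPU in minutes: 32^3 grid, 3 levels, base 8 features, N=50, M=100,
  500 iterations, with phantom/deformation geometry scaled to the grid.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np
import yaml

from propnet.errors import ConfigError
from propnet.evaluation import default_grid_spec
from propnet.network import (
    LossWeights,
    OptimizerSettings,
    ProgressiveSchedule,
    UNetConfig,
)
from propnet.phantom import PhantomSpec
from propnet.volume import NetworkGridSpec

_PAPER = {
    "phantom": {
        "grid": [128, 128, 128],
        "spacing": [1.5625, 1.5625, 0.9375],
        "n_patients": 5,
        "n_fractions": 20,
    },
    "network": {
        "levels": 5,
        "input_size": [128, 128, 128],
        "base_features": 32,
        "feature_cap": 256,
    },
    "schedule": {"N": 1000, "M": 2000},
    "loss": {"preset": "hybrid"},
    "optimizer": {"learning_rate": 0.01, "momentum": 0.5},
    "iterations": 15000,
    "seed": 0,
    "shifts_mm": list(range(-5, 6)),
}

_DESK = {
    "phantom": {
        "grid": [32, 32, 32],
        "spacing": [6.25, 6.25, 3.75],
        "n_patients": 5,
        "n_fractions": 5,
    },
    "network": {
        "levels": 3,
        "input_size": [32, 32, 32],
        "base_features": 8,
        "feature_cap": 256,
    },
    "schedule": {"N": 50, "M": 100},
    "loss": {"preset": "hybrid"},
    "optimizer": {"learning_rate": 0.01, "momentum": 0.5},
    "iterations": 500,
    "seed": 0,
    "shifts_mm": list(range(-5, 6)),
}

PROFILES = {"paper": _PAPER, "desk": _DESK}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


class RunConfig:
    """A resolved configuration: profile defaults + YAML file + CLI overrides."""

    def __init__(self, raw: dict):
        self.raw = raw
        try:
            self._build()
        except ConfigError:
            raise
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def resolve(cls, profile: str = "desk", config_path: Optional[str] = None,
                overrides: Optional[dict] = None) -> "RunConfig":
        if profile not in PROFILES:
            raise ConfigError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        raw = copy.deepcopy(PROFILES[profile])
        if config_path is not None:
            with open(config_path) as fh:
                user = yaml.safe_load(fh) or {}
            if not isinstance(user, dict):
                raise ConfigError(f"{config_path} must hold a YAML mapping")
            raw = _merge(raw, user)
        if overrides:
            raw = _merge(raw, overrides)
        return cls(raw)

    def _build(self):
        r = self.raw
        ph = r["phantom"]
        self.phantom_spec = PhantomSpec(
            grid=tuple(ph["grid"]), spacing=tuple(ph["spacing"]),
            **{k: v for k, v in ph.items()
               if k not in ("grid", "spacing", "n_patients", "n_fractions")},
        )
        self.n_patients = int(ph.get("n_patients", 5))
        self.n_fractions = int(ph.get("n_fractions", 5))
        if self.n_patients < 1 or self.n_fractions < 1:
            raise ConfigError("phantom.n_patients and phantom.n_fractions "
                              "must be >= 1")
        nw = r["network"]
        self.network = UNetConfig(
            levels=int(nw["levels"]), input_size=tuple(nw["input_size"]),
            base_features=int(nw["base_features"]),
            feature_cap=int(nw.get("feature_cap", 256)),
        )
        self.grid_spec = default_grid_spec(self.network.input_size)
        sc = r["schedule"]
        self.schedule = ProgressiveSchedule(N=int(sc["N"]), M=int(sc["M"]))
        lo = r["loss"]
        if "preset" in lo:
            self.loss = LossWeights.from_preset(lo["preset"])
        else:
            self.loss = LossWeights(k_overlap=float(lo["k_overlap"]),
                                    k_dvf=float(lo["k_dvf"]))
        op = r["optimizer"]
        self.optimizer = OptimizerSettings(
            learning_rate=float(op["learning_rate"]),
            momentum=float(op["momentum"]))
        self.iterations = int(r["iterations"])
        self.seed = int(r["seed"])
        if not (0 <= self.seed < 2**31):
            raise ConfigError("seed must lie in [0, 2^31)")
        self.shifts_mm = [float(s) for s in r["shifts_mm"]]

    def dump(self) -> str:
        """The fully resolved configuration as YAML (for run logs)."""
        return yaml.safe_dump(self.raw, sort_keys=True)

    def patient_rng(self, index: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, 100, index])
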