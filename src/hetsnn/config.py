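"""Structured run configuration: YAML round-trip, strict validation, builders.

The configuration mirrors the library objects (neuron parameters, STDP
parameters, layer stack, schedule, synthetic-data specs).  Unknown keys are
rejected with their full path, so typos fail loudly instead of silently
falling back to defaults.  One global seed fans out to named sub-seeds
(data, encoding/shuffling, readout) so components can be re-run
independently.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .network import ConvLayerSpec, NetworkConfig
from .plasticity import StdpParams
from .synthetic import MotionSpec, default_sprites, make_dataset
from .training import TrainSchedule

__all__ = ["RunConfig", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "out",
    "encoding": {"f_max": 100.0, "mode": "poisson"},
    "stdp": {
        "alpha_p": 0.1, "alpha_d": 0.03, "G_max": 1.0, "G_min": 0.0,
        "tau_pot": 10.0, "tau_dep": 80.0, "ltd_window": 50.0,
    },
    "network": {
        "input_shape": [32, 32],
        "local_radius": 1,
        "learner_gap": 0.6,
        "memory_gaps": {"long_term": 0.15, "short_term": 0.8},
        "layers": [
            {"kernel": [5, 5], "depth": 6, "stride": 2, "threshold_scale": 1.0},
        ],
        "sections": [["class", 2], ["translation", 2]],
    },
    "schedule": {
        "t_train": 50.0, "epochs_per_layer": 1,
        "readout_lr": 0.2, "readout_epochs": 400, "readout_batch": 16,
    },
    "data": {
        "canvas": [32, 32], "n_frames": 10, "n_classes": 2, "sprite_size": 10,
        "sigma_ts": 1.0, "n_train_per_combo": 6, "n_test_per_combo": 6,
        "translation": [
            {"kind": "constant", "speed": 2.0, "direction": [0, 1]},
            {"kind": "oscillating", "amplitude": 4.0, "period": 8, "direction": [0, 1]},
        ],
        "rotation": [{"kind": "static"}],
    },
}

_MOTION_KEYS = {"kind", "speed", "acceleration", "amplitude", "period", "direction"}
_LAYER_KEYS = {"kernel", "depth", "stride", "threshold_scale", "memory_mix"}

_SCHEMA: dict = {
    "seed": None,
    "output_dir": None,
    "encoding": {"f_max": None, "mode": None},
    "stdp": {k: None for k in DEFAULT_CONFIG["stdp"]},
    "network": {
        "input_shape": None, "local_radius": None, "learner_gap": None,
        "memory_gaps": {"long_term": None, "short_term": None},
        "layers": [_LAYER_KEYS], "sections": None,
    },
    "schedule": {k: None for k in DEFAULT_CONFIG["schedule"]},
    "data": {
        "canvas": None, "n_frames": None, "n_classes": None, "sprite_size": None,
        "sigma_ts": None, "n_train_per_combo": None, "n_test_per_combo": None,
        "translation": [_MOTION_KEYS], "rotation": [_MOTION_KEYS],
    },
}


def _validate(data: Any, schema: Any, path: str = "") -> None:
    if schema is None:
        return
    if isinstance(schema, dict):
        if not isinstance(data, dict):
            raise ValueError(f"config{path}: expected a mapping")
        for key, val in data.items():
            if key not in schema:
                raise ValueError(f"config{path}: unknown key {key!r}")
            _validate(val, schema[key], f"{path}.{key}")
    elif isinstance(schema, list):
        if not isinstance(data, list):
            raise ValueError(f"config{path}: expected a list")
        for i, item in enumerate(data):
            if not isinstance(item, dict):
                raise ValueError(f"config{path}[{i}]: expected a mapping")
            for key in item:
                if key not in schema[0]:
                    raise ValueError(f"config{path}[{i}]: unknown key {key!r}")
    elif isinstance(schema, set):
        raise AssertionError("set schema must be wrapped in a list")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


class RunConfig:
    """Validated run configuration with builders for the library objects."""

    def __init__(self, data: dict | None = None):
        data = data or {}
        _validate(data, _SCHEMA)
        self.data = _merge(DEFAULT_CONFIG, data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(raw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    # -- named sub-seeds ----------------------------------------------------

    def sub_seed(self, name: str) -> int:
        h = hashlib.sha256(f"{self.data['seed']}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    # -- builders -----------------------------------------------------------

    def build_stdp(self) -> StdpParams:
        return StdpParams(**self.data["stdp"])

    def build_network_config(self) -> NetworkConfig:
        net = self.data["network"]
        layers = [
            ConvLayerSpec(
                kernel=tuple(l["kernel"]), depth=l["depth"],
                stride=l.get("stride", 2),
                threshold_scale=l.get("threshold_scale", 1.0),
                memory_mix=tuple(l.get("memory_mix", ("long_term", "short_term"))),
            )
            for l in net["layers"]
        ]
        return NetworkConfig(
            input_shape=tuple(net["input_shape"]),
            layers=layers,
            mopm_sections=[(str(n), int(k)) for n, k in net["sections"]],
            local_radius=net["local_radius"],
            seed=self.sub_seed("network-init"),
            learner_gap=net["learner_gap"],
            memory_gaps=dict(net["memory_gaps"]),
            stdp=self.build_stdp(),
        )

    def build_schedule(self) -> TrainSchedule:
        sch = self.data["schedule"]
        enc = self.data["encoding"]
        return TrainSchedule(
            t_train=sch["t_train"], f_max=enc["f_max"], encode_mode=enc["mode"],
            seed=self.sub_seed("schedule"),
            epochs_per_layer=sch["epochs_per_layer"],
            readout_lr=sch["readout_lr"], readout_epochs=sch["readout_epochs"],
            readout_batch=sch["readout_batch"],
        )

    def _motions(self, which: str) -> list[MotionSpec]:
        applies = "translation" if which == "translation" else "rotation"
        out = []
        for m in self.data["data"][which]:
            kw = dict(m)
            if "direction" in kw:
                kw["direction"] = tuple(kw["direction"])
            out.append(MotionSpec(applies_to=applies, **kw))
        return out

    def build_dataset(self):
        d = self.data["data"]
        sprites = default_sprites(d["n_classes"], size=d["sprite_size"])
        return make_dataset(
            sprites,
            self._motions("translation"),
            self._motions("rotation"),
            sigma_ts=d["sigma_ts"],
            n_train_per_combo=d["n_train_per_combo"],
            n_test_per_combo=d["n_test_per_combo"],
            canvas=tuple(d["canvas"]),
            n_frames=d["n_frames"],
            seed=self.sub_seed("data"),
        )
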