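"""Run configuration: YAML loading, validation, and profiles.

A run config has four sections — ``phantom``, ``network``, ``train``,
``swarm`` — each mapping onto the corresponding dataclass.  Unknown keys
are rejected with the offending names.  The ``network.profile`` selects
between the documented default widths ("full": stage channels
256/138/128/64) and a reduced configuration for CPU-scale experiments
("desk"), which also raises the learning rate to suit the much smaller
parameter count.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .fss import SwarmConfig
from .network import DEFAULT_MULTI_CHANNELS, NetworkSpec, multi_stream_spec
from .phantoms import PhantomSpec
from .training import TrainConfig

__all__ = ["PROFILES", "RunConfig", "load_config"]

# desk: reduced channel widths + a learning rate suited to the small model;
# the full documented widths remain the default
PROFILES = {
    "full": {"channels": DEFAULT_MULTI_CHANNELS, "train": {}},
    "desk": {"channels": (12, 10, 12, 8), "train": {"lr0": 0.03}},
}

_NETWORK_KEYS = {"profile", "channels", "image_size", "dropout_rate", "arch"}


def _filter_fields(section: str, data: dict, cls):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown keys in [{section}]: {sorted(unknown)}; "
            f"valid keys are {sorted(valid)}"
        )
    return data


@dataclasses.dataclass
class RunConfig:
    phantom: PhantomSpec
    network: dict
    train: TrainConfig
    swarm: SwarmConfig
    seed: int = 0

    def network_spec(self) -> NetworkSpec:
        net = self.network
        profile = PROFILES[net.get("profile", "full")]
        channels = tuple(net.get("channels") or profile["channels"])
        image_size = net.get("image_size", self.phantom.image_size)
        dropout = net.get("dropout_rate", 0.25)
        if net.get("arch", "multi") == "single":
            return NetworkSpec(
                image_size=image_size,
                stream_channels=(channels,),
                dropout_rate=dropout,
                allow_nonstandard=len(channels) != 4,
            )
        return multi_stream_spec(channels, image_size, dropout)

    def as_dict(self) -> dict:
        return {
            "phantom": dataclasses.asdict(self.phantom),
            "network": dict(self.network),
            "train": dataclasses.asdict(self.train),
            "swarm": dataclasses.asdict(self.swarm),
            "seed": self.seed,
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides.

    Precedence (highest wins): overrides > file values > profile values >
    dataclass defaults.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    known_sections = {"phantom", "network", "train", "swarm", "seed"}
    unknown = set(data) - known_sections
    if unknown:
        raise ValueError(
            f"unknown config sections: {sorted(unknown)}; "
            f"valid sections are {sorted(known_sections)}"
        )
    overrides = overrides or {}
    seed = overrides.get("seed", data.get("seed", 0))

    net = dict(data.get("network", {}))
    unknown = set(net) - _NETWORK_KEYS
    if unknown:
        raise ValueError(
            f"unknown keys in [network]: {sorted(unknown)}; "
            f"valid keys are {sorted(_NETWORK_KEYS)}"
        )
    net.update({k: v for k, v in overrides.items()
                if k in _NETWORK_KEYS and v is not None})

    phantom_kw = _filter_fields("phantom", dict(data.get("phantom", {})), PhantomSpec)
    if "kidney_axes" in phantom_kw:
        phantom_kw["kidney_axes"] = tuple(phantom_kw["kidney_axes"])

    profile_train = dict(PROFILES[net.get("profile", "full")]["train"])
    train_kw = {**profile_train,
                **_filter_fields("train", dict(data.get("train", {})), TrainConfig)}
    train_kw.update({k: v for k, v in overrides.items()
                     if k in {f.name for f in dataclasses.fields(TrainConfig)}
                     and v is not None})
    train_kw["seed"] = train_kw.get("seed", seed)

    swarm_kw = _filter_fields("swarm", dict(data.get("swarm", {})), SwarmConfig)
    if "bounds" in swarm_kw:
        swarm_kw["bounds"] = tuple(tuple(b) for b in swarm_kw["bounds"])

    return RunConfig(
        phantom=PhantomSpec(**phantom_kw),
        network=net,
        train=TrainConfig(**train_kw),
        swarm=SwarmConfig(**swarm_kw),
        seed=seed,
    )
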