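"""Run configuration: structured, validated, fully serialized with outputs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError


def _check_keys(cls, data: dict, path: str) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path}: {sorted(unknown)}")


def _check_number(value, key: str):
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"config key {key}: expected a number, got {value!r}")
    return value


@dataclass
class Thresholds:
    z_thr: float = -3.0
    rate_thr: float = 0.6
    lfc_thr: float = -1.0
    on_thr: float = 0.5
    off_thr: float = 1.0
    min_r_wt: float = 0.5

    def __post_init__(self):
        for f in fields(self):
            _check_number(getattr(self, f.name), f"thresholds.{f.name}")


@dataclass
class ScreenParams:
    depth: float = 700.0
    n_reps: int = 3
    nb_size: float = 100.0


@dataclass
class DualTargetParams:
    depth: int = 2000


@dataclass
class OnTargetParams:
    hidden: int = 24
    pretrain_epochs: int = 200
    pretrain_n: int = 1500
    features: str = "mono+di"
    hidden_layer_sizes: tuple = (64, 16)
    max_iter: int = 300


@dataclass
class GenomeParams:
    size_bp: int = 60000
    n_planted_quiet: int = 2
    n_planted_promiscuous: int = 6
    max_mm: int = 3


@dataclass
class RunConfig:
    """Top-level configuration of the end-to-end demo recipe."""

    seed: int = 0
    n_guides: int = 2000
    thresholds: Thresholds = field(default_factory=Thresholds)
    screen: ScreenParams = field(default_factory=ScreenParams)
    dualtarget: DualTargetParams = field(default_factory=DualTargetParams)
    ontarget: OnTargetParams = field(default_factory=OnTargetParams)
    genome: GenomeParams = field(default_factory=GenomeParams)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _check_keys(cls, data, "<root>")
        kwargs = dict(data)
        for name, sub in (
            ("thresholds", Thresholds),
            ("screen", ScreenParams),
            ("dualtarget", DualTargetParams),
            ("ontarget", OnTargetParams),
            ("genome", GenomeParams),
        ):
            if name in kwargs:
                block = kwargs[name]
                if not isinstance(block, dict):
                    raise ConfigError(f"config key {name}: expected a mapping")
                _check_keys(sub, block, name)
                try:
                    kwargs[name] = sub(**block)
                except ConfigError:
                    raise
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"config block {name}: {exc}") from exc
        if "seed" in kwargs:
            _check_number(kwargs["seed"], "seed")
        if "n_guides" in kwargs:
            _check_number(kwargs["n_guides"], "n_guides")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ontarget"]["hidden_layer_sizes"] = list(
            d["ontarget"]["hidden_layer_sizes"]
        )
        return d
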