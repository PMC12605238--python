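"""Typed pipeline configuration with strict validation and hashing.

The configuration tree mirrors the pipeline stages (simulation,
preprocessing, networks, model, evaluation). Unknown keys are rejected so
that typos fail loudly, and every run artifact records the SHA-256 hash of
the canonical JSON form of its configuration, which the evaluation stage
uses to refuse mixed-provenance inputs. Defaults reproduce the 1-40-0.5
scheme: first-order Chebyshev convolution, 40 time points, dropout 0.5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .mgcn import TrainConfig
from .mi_labeling import DNNConfig
from .synthetic_data import SimulationSpec


def _from_dict(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) at {path or 'top level'}: "
            f"{sorted(unknown)}"
        )
    return cls(**{f.name: data[f.name] for f in fields(cls)
                  if f.name in data})


@dataclass(frozen=True)
class PreprocessConfig:
    cognitive_filter: tuple[float, float, int] = (0.5, 20.0, 3)
    mi_filter: tuple[float, float, int] = (8.0, 30.0, 5)
    baseline: tuple[float, float] = (0.0, 0.2)
    crop_window: tuple[float, float] = (0.2, 1.2)


@dataclass(frozen=True)
class NetworkConfig:
    downsample_points: int = 40
    band_backend: str = "bandpass"
    plv_aggregation: str = "mean"
    md_convention: str = "similarity"
    welch_nperseg: int | None = None

    def __post_init__(self) -> None:
        if self.downsample_points not in (20, 40, 60):
            raise ValueError(
                f"downsample_points must be one of 20/40/60, got "
                f"{self.downsample_points}"
            )
        if self.band_backend not in ("bandpass", "dwt"):
            raise ValueError(f"unknown band backend {self.band_backend!r}")
        if self.plv_aggregation not in ("mean", "max"):
            raise ValueError(
                f"unknown PLV aggregation {self.plv_aggregation!r}"
            )
        if self.md_convention not in ("similarity", "distance"):
            raise ValueError(f"unknown MD convention {self.md_convention!r}")


@dataclass(frozen=True)
class EvaluationConfig:
    binarize_threshold: float = 0.3
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.binarize_threshold < 1):
            raise ValueError("binarize_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    model: TrainConfig = field(default_factory=TrainConfig)
    labeling: DNNConfig = field(default_factory=DNNConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    _SECTIONS = {
        "simulation": SimulationSpec,
        "preprocessing": PreprocessConfig,
        "network": NetworkConfig,
        "model": TrainConfig,
        "labeling": DNNConfig,
        "evaluation": EvaluationConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                sec = dict(data[name])
                for f in fields(section_cls):
                    if f.name in sec and isinstance(sec[f.name], list):
                        sec[f.name] = tuple(sec[f.name])
                kwargs[name] = _from_dict(section_cls, sec, name)
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_overrides(self, overrides: dict[str, object]) -> "PipelineConfig":
        """Apply dotted-path overrides, e.g. {"model.epochs": 200}."""
        data = self.to_dict()
        for key, value in overrides.items():
            parts = key.split(".")
            node = data
            for p in parts[:-1]:
                if p not in node:
                    raise ValueError(f"unknown override path {key!r}")
                node = node[p]
            if parts[-1] not in node:
                raise ValueError(f"unknown override path {key!r}")
            node[parts[-1]] = value
        return PipelineConfig.from_dict(data)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: convert(getattr(obj, f.name))
                        for f in fields(obj)}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            return obj
        out = {name: convert(getattr(self, name)) for name in self._SECTIONS}
        out["seed"] = self.seed
        return out

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True,
                          separators=(",", ":"))

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Propagate one top-level seed into every seeded stage."""
        return self.with_overrides({
            "seed": seed,
            "simulation.seed": seed,
            "model.seed": (seed * 2654435761) % 2**31,
            "labeling.seed": (seed + 1) % 2**31,
        })
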