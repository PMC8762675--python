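"""Run configuration: one structured YAML file governs every stage.

Unknown keys are rejected everywhere so silent typos cannot change an
analysis; every run writes a manifest capturing the exact configuration
and per-stage counts needed to re-run it bit-identically.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .forest import ModelParams
from .io import write_json_atomic
from .simulate import GroundTruthSF, SimulationConfig, reduced_config


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class FilterParams:
    spatial_sigma: float = 3.0
    range_sigma: float | None = None
    target_inner_mean: float = 100.0


@dataclass(frozen=True)
class SpotParams:
    thickness_spot_um: float = 288.0
    intensity_spot_um: float = 576.0


@dataclass(frozen=True)
class ExclusionPolicy:
    groups: tuple[str, ...] = ("4",)
    eyes: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs, resolved and validated."""

    output_dir: Path
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filtering: FilterParams = field(default_factory=FilterParams)
    spots: SpotParams = field(default_factory=SpotParams)
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    model: ModelParams = field(default_factory=ModelParams)

    @staticmethod
    def from_dict(raw: dict, overrides: dict | None = None) -> "RunConfig":
        raw = dict(raw or {})
        for k, v in (overrides or {}).items():
            if v is not None:
                raw[k] = v
        _check_keys(
            raw,
            {"output_dir", "seed", "simulation", "filtering", "spots",
             "exclusions", "model"},
            "run config",
        )
        if "output_dir" not in raw:
            raise ConfigError("output_dir is required")
        seed = int(raw.get("seed", 0))

        sim_raw = dict(raw.get("simulation") or {})
        preset = sim_raw.pop("preset", "default")
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        _check_keys(sim_raw, sim_fields, "simulation")
        if "sf_params" in sim_raw:
            sf_raw = dict(sim_raw["sf_params"])
            _check_keys(
                sf_raw, {f.name for f in dataclasses.fields(GroundTruthSF)},
                "simulation.sf_params",
            )
            sim_raw["sf_params"] = GroundTruthSF(**sf_raw)
        if "volume_shape" in sim_raw:
            sim_raw["volume_shape"] = tuple(sim_raw["volume_shape"])
        if "n_patients_per_group" in sim_raw:
            sim_raw["n_patients_per_group"] = {
                str(k): int(v) for k, v in sim_raw["n_patients_per_group"].items()
            }
        sim_raw.setdefault("seed", seed)
        if preset == "reduced":
            simulation = reduced_config(**sim_raw)
        elif preset == "default":
            simulation = SimulationConfig(**sim_raw)
        else:
            raise ConfigError(f"unknown simulation preset {preset!r}")

        def build(cls, key):
            sub = dict(raw.get(key) or {})
            _check_keys(sub, {f.name for f in dataclasses.fields(cls)}, key)
            for name in ("groups", "eyes"):
                if name in sub:
                    sub[name] = tuple(str(x) for x in sub[name])
            return cls(**sub)

        model_raw = dict(raw.get("model") or {})
        _check_keys(
            model_raw, {f.name for f in dataclasses.fields(ModelParams)}, "model"
        )
        model_raw.setdefault("seed", seed)

        return RunConfig(
            output_dir=Path(raw["output_dir"]),
            seed=seed,
            simulation=simulation,
            filtering=build(FilterParams, "filtering"),
            spots=build(SpotParams, "spots"),
            exclusions=build(ExclusionPolicy, "exclusions"),
            model=ModelParams(**model_raw),
        )

    @staticmethod
    def from_yaml(path: Path, overrides: dict | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return RunConfig.from_dict(raw, overrides)

    def snapshot(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)


class RunManifest:
    """Accumulates per-stage counts/warnings/timings; written atomically."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.path = Path(config.output_dir) / "manifest.json"
        self.stages: dict[str, dict] = {}
        if self.path.exists():
            import json

            try:
                self.stages = json.loads(self.path.read_text()).get("stages", {})
            except ValueError:
                self.stages = {}

    def record(self, stage: str, t_start: float, **info) -> None:
        self.stages[stage] = {
            "elapsed_s": round(time.monotonic() - t_start, 3),
            **info,
        }
        self.write()

    def write(self) -> None:
        payload = {
            "package_version": __version__,
            "config": self.config.snapshot(),
            "stages": self.stages,
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        write_json_atomic(payload, self.path)
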