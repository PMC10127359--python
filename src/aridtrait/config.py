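"""Run configuration: YAML schema, validation, and seeded substreams.

A single config seed drives every stage through named substreams (the stage
name is hashed into the seed sequence), so adding or reordering stages never
perturbs another stage's draws. A resolved copy of the configuration is
written into every output directory for reproducibility.
"""
from __future__ import annotations

import dataclasses
import zlib
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .synthetic import AssayConfig, SpeciesParams

KNOWN_STAGES = ("simulate", "derive", "signal", "fit-general", "fit-relative")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed and stage name."""
    mix = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    seed: int = 0
    horizon_h: float = 96.0
    trials_unit_h: float = 0.5
    n_randomizations: int = 999
    alpha: float = 0.05
    reference_species: str | None = None
    include_fwc: bool = True
    stages: list[str] = dataclasses.field(
        default_factory=lambda: list(KNOWN_STAGES)
    )
    tree_path: str | None = None
    individuals_path: str | None = None
    weighings_path: str | None = None
    simulation: dict[str, Any] = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ConfigError(
                f"unknown stage(s) {unknown}; known stages: {list(KNOWN_STAGES)}"
            )
        if self.horizon_h <= 0:
            raise ConfigError("horizon_h must be positive")
        if self.n_randomizations < 99:
            raise ConfigError("n_randomizations must be >= 99")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def assay_config(self) -> AssayConfig:
        """Build the simulation's AssayConfig from the ``simulation`` block."""
        sim = self.simulation
        if "species" not in sim or not sim["species"]:
            raise ConfigError("simulation.species table is missing or empty")
        species_params: dict[str, SpeciesParams] = {}
        n_individuals: dict[str, int] = {}
        for name, raw in sim["species"].items():
            raw = dict(raw)
            n_individuals[name] = int(raw.pop("n_individuals"))
            try:
                species_params[name] = SpeciesParams(**raw)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"species {name!r}: {exc}") from exc
        return AssayConfig(
            species_params=species_params,
            n_individuals=n_individuals,
            horizon_h=self.horizon_h,
            daily_weigh_times_h=tuple(
                sim.get("daily_weigh_times_h", (9.0, 12.0, 15.0, 18.0))
            ),
            day_length_h=float(sim.get("day_length_h", 24.0)),
            measurement_noise_sd_mg=float(sim.get("measurement_noise_sd_mg", 0.0)),
            seed=stage_seed(self.seed, "simulate"),
        )


def config_from_dict(raw: dict) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    extra = set(raw) - known
    if extra:
        raise ConfigError(f"unknown config keys: {sorted(extra)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def default_config() -> RunConfig:
    """The packaged demo configuration: an 8-species, 3-guild assay with
    species-level scales in the ranges reported for north temperate dung
    beetles, 96 h horizon, 0.1 mg balance noise."""
    text = (
        resources.files("aridtrait").joinpath("data/default_config.yaml").read_text()
    )
    return config_from_dict(yaml.safe_load(text))


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
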