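"""Model configuration loading: PK registry, potency table, surface, settings."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .opioid_equivalence import PotencyTable
from .pd_surface import SurfaceParameters
from .pk_models import PKParameters
from .simulation import SimulationSettings

__all__ = ["ModelConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to simulate a regimen."""

    pk_registry: Mapping[str, PKParameters]
    potency: PotencyTable
    surface: SurfaceParameters
    settings: SimulationSettings


def _parse(data: dict) -> ModelConfig:
    registry = {}
    for drug, block in data["pk_registry"].items():
        registry[drug] = PKParameters(drug_name=drug, **block)
    pot = data["potency"]
    potency = PotencyTable(factors=dict(pot["factors"]), ce_units=dict(pot["ce_units"]))
    surface = SurfaceParameters(**data["surface"])
    settings = SimulationSettings(**data.get("settings", {}))
    return ModelConfig(pk_registry=registry, potency=potency, surface=surface, settings=settings)


def load_config(path: str | Path) -> ModelConfig:
    """Load a model configuration YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _parse(data)


def default_config() -> ModelConfig:
    """The packaged default configuration for the reference patient."""
    ref = resources.files("sedsim.data").joinpath("default_config.yaml")
    return _parse(yaml.safe_load(ref.read_text()))
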