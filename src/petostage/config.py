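"""Study configuration: species, tissues, scaling exponents, risk target.

The default configuration ships the study's constants so every pipeline
entry point runs with zero arguments.  A YAML or JSON file with the same
schema can override any of it (see ``data/default_config.yaml``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .allometry import HUMAN, SpeciesSpec, TissueSpec

__all__ = ["StudyConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class StudyConfig:
    """Everything the pipeline needs to rebuild the full results table."""

    baseline_species: SpeciesSpec
    target_species: tuple[SpeciesSpec, ...]
    tissues: tuple[TissueSpec, ...]
    reference_species: SpeciesSpec = field(default=HUMAN)
    betas: tuple[float, ...] = (0.0, -0.15, -0.3)
    p_target: float = 0.01
    u_anchor: float = 1e-5
    M_max: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.p_target < 1.0:
            raise ValueError(f"p_target must be in (0, 1), got {self.p_target}")
        if not self.u_anchor > 0:
            raise ValueError(f"u_anchor must be > 0, got {self.u_anchor}")
        if self.M_max < 2:
            raise ValueError(f"M_max must be >= 2, got {self.M_max}")


def _species(d: dict) -> SpeciesSpec:
    return SpeciesSpec(d["name"], float(d["weight"]), float(d["lifespan"]))


def _tissue(d: dict) -> TissueSpec:
    return TissueSpec(d["name"], float(d["C_ref"]), float(d["k_ref"]))


def _from_mapping(data: dict) -> StudyConfig:
    species = {d["name"]: _species(d) for d in data["species"]}
    return StudyConfig(
        baseline_species=species[data["baseline_species"]],
        target_species=tuple(species[n] for n in data["target_species"]),
        tissues=tuple(_tissue(d) for d in data["tissues"]),
        reference_species=species[data["reference_species"]],
        betas=tuple(float(b) for b in data.get("betas", (0.0, -0.15, -0.3))),
        p_target=float(data.get("p_target", 0.01)),
        u_anchor=float(data.get("u_anchor", 1e-5)),
        M_max=int(data.get("M_max", 10)),
    )


def load_config(path: str | Path) -> StudyConfig:
    """Load a study configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _from_mapping(data)


def default_config() -> StudyConfig:
    """The packaged default: mouse baseline, human/whale targets,
    the three tissues, betas {0, -0.15, -0.3}, 1% risk target."""
    ref = resources.files("petostage.data").joinpath("default_config.yaml")
    return _from_mapping(yaml.safe_load(ref.read_text()))
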