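"""Analysis configuration.

Defaults mirror the experimental set-up the analysis chain assumes: a 10 mL
recirculating perfusate reservoir sampled with 250 uL replacement draws for the
isolated perfused mouse lung (IPML), 3 mL Ussing half-chambers sampled with
1 mL replacement draws across a 0.12 cm^2 exposed intestinal segment, and a
75 s solvent front on the IAM column.
"""
from __future__ import annotations

import dataclasses
import pathlib
import tomllib
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = ["OplsSettings", "AnalysisConfig"]


@dataclass
class OplsSettings:
    """Settings for the OPLS-DA classifier.

    ``cv_scheme`` selects how Q2 is cross-validated: ``"refit_all"``
    re-estimates scaling and every component inside each training fold;
    ``"fixed_orthogonal"`` keeps the full-model orthogonal filter and
    cross-validates the predictive component only (the convention under
    which commercial chemometrics software reports Q2 for orthogonal-filtered
    models; see docs/methods.md).
    """

    n_orthogonal: int = 1
    folds: int = 7
    y_coding: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 1.0}
    )
    threshold: float = 0.5
    cv_scheme: str = "refit_all"

    def __post_init__(self) -> None:
        if self.n_orthogonal != "auto" and int(self.n_orthogonal) < 0:
            raise ValueError("n_orthogonal must be >= 0 or 'auto'")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.cv_scheme not in ("refit_all", "fixed_orthogonal"):
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")
        if set(self.y_coding) != {"A", "B"}:
            raise ValueError("y_coding must map exactly the labels A and B")


@dataclass
class AnalysisConfig:
    reservoir_volume_mL: float = 10.0
    sample_volume_mL: float = 0.25
    ussing_chamber_volume_mL: float = 3.0
    ussing_sample_volume_mL: float = 1.0
    exposed_area_cm2: float = 0.12
    solvent_front_s: float = 75.0
    oplsda: OplsSettings = field(default_factory=OplsSettings)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "reservoir_volume_mL",
            "sample_volume_mL",
            "ussing_chamber_volume_mL",
            "ussing_sample_volume_mL",
            "exposed_area_cm2",
            "solvent_front_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sample_volume_mL >= self.reservoir_volume_mL:
            raise ValueError("sample volume must be smaller than the reservoir")
        if self.ussing_sample_volume_mL >= self.ussing_chamber_volume_mL:
            raise ValueError("sample volume must be smaller than the chamber")
        if isinstance(self.oplsda, Mapping):
            self.oplsda = OplsSettings(**self.oplsda)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "AnalysisConfig":
        """Load a TOML or YAML configuration file (selected by extension)."""
        path = pathlib.Path(path)
        if path.suffix.lower() == ".toml":
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        elif path.suffix.lower() in (".yaml", ".yml"):
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        else:
            raise ValueError(f"unsupported config format: {path.suffix!r}")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["oplsda"]["y_coding"] = dict(d["oplsda"]["y_coding"])
        return d
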