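"""Run configuration: one document that pins every production setting.

Defaults reproduce the production method: Δλ = 50 nm, 9-point
second-order Savitzky-Golay first derivative, auto-selected analytical
wavelengths, the default band models and noise, and a single seed from
which all randomness flows.  Configs load from YAML or TOML.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .simulate import (
    DEFAULT_DELTA_LAMBDA,
    DEFAULT_EM_GRID,
    DEFAULT_EX_GRID,
    NoiseModel,
)
from .spectra import WavelengthGrid

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    delta_lambda: float = DEFAULT_DELTA_LAMBDA
    window_points: int = 9
    poly_order: int = 3
    #: None means: auto-select at the interferent zero-crossings.
    lambda_A: float | None = None
    lambda_B: float | None = None
    wavelength_tolerance: float = 2.0
    ex_start: float = DEFAULT_EX_GRID.start
    ex_stop: float = DEFAULT_EX_GRID.stop
    em_start: float = DEFAULT_EM_GRID.start
    em_stop: float = DEFAULT_EM_GRID.stop
    step: float = 1.0
    additive_sd: float = NoiseModel().additive_sd
    proportional_sd: float = NoiseModel().proportional_sd
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0 or self.window_points <= self.poly_order:
            raise ValueError("window_points must be odd and > poly_order")
        if self.delta_lambda <= 0:
            raise ValueError("delta_lambda must be positive")

    @property
    def ex_grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.ex_start, self.ex_stop, self.step)

    @property
    def em_grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.em_start, self.em_stop, self.step)

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.additive_sd, self.proportional_sd, self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (.yml/.yaml) or TOML (.toml) config; None gives defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text(encoding="utf-8"))
    else:
        data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
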