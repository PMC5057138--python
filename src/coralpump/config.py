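"""Run configuration: YAML/JSON schema, validation and object construction.

Defaults mirror the study conditions: a 200–2000 m shelf-slope domain at
250-m spacing with a 380-m coral mound (summit 600 m) and a 450-m shelf-break
ridge, 32 sigma levels stretched with theta_s = 3.4 and theta_b = 1, a
semidiurnal tide with spring–neap modulation stored at 6-h cadence, and the
organic-matter parameters ws = 20 m/d, k = 0.03 1/d, F0 = 12 mmol C m-2 d-1
and suspension-feeding enhancement 10.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import synthflow
from .grid import Bathymetry, SigmaGrid, build_grid
from .omreaction import OMParams, ScenarioConfig
from .synthflow import HabitatMask, TidalForcing


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridBlock(_Block):
    n_levels: int = Field(32, ge=2)
    theta_s: float = Field(3.4, ge=0.0)
    theta_b: float = Field(1.0, ge=0.0, le=1.0)


class MoundBlock(_Block):
    x: float
    y: float
    relief: float = Field(gt=0)
    radius: float = Field(gt=0)


class RidgeBlock(_Block):
    x: float
    crest_depth: float = Field(gt=0)
    width: float = Field(gt=0)


class BathymetryBlock(_Block):
    nx: int = Field(60, ge=4)
    ny: int = Field(40, ge=4)
    dx: float = Field(250.0, gt=0)
    dy: float = Field(250.0, gt=0)
    shelf_depth: float = Field(200.0, gt=0)
    trough_depth: float = Field(2000.0, gt=0)
    slope_break: Optional[float] = None
    slope_width: Optional[float] = None
    mounds: Optional[list[MoundBlock]] = None  # None -> study defaults
    ridge: Optional[RidgeBlock] = None

    @model_validator(mode="after")
    def _deeper_trough(self):
        if self.trough_depth <= self.shelf_depth:
            raise ValueError("trough_depth must exceed shelf_depth")
        return self


class ForcingBlock(_Block):
    u_amplitude: float = Field(0.3, gt=0)
    tidal_period: float = Field(12.42, gt=0)
    springneap_period: float = Field(14.77, gt=0)
    modulation: float = Field(0.4, ge=0, lt=1)
    direction: float = 0.0
    reference_depth: float = Field(600.0, gt=0)
    surface_intensification: float = Field(1.0, ge=0)
    intensification_scale: float = Field(300.0, gt=0)
    transport_scaling: str = "background"
    background_transport: float = 0.0
    cadence_hours: float = Field(6.0, gt=0)


class HabitatBlock(_Block):
    summit_window: tuple[float, float] = (400.0, 1000.0)
    slope_threshold: float = Field(20.0, ge=0)
    ridge_window: tuple[float, float] = (400.0, 550.0)
    coverage: float = Field(0.4, gt=0, le=1)


class OMBlock(_Block):
    ws: float = Field(20.0, gt=0)
    k_decay: float = Field(0.03, gt=0)
    surface_flux: float = Field(12.0, gt=0)
    enhancement: float = Field(10.0, gt=0)


class ScenarioBlock(_Block):
    filtration_on: bool = True
    hydrodynamics_on: bool = True
    t_start: float = 0.0
    t_end: float = 34.54
    output_cadence: float = Field(0.25, gt=0)
    spinup: float = Field(5.0, ge=0)

    @model_validator(mode="after")
    def _span(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.spinup >= self.t_end - self.t_start:
            raise ValueError("spinup must fall inside the run interval")
        return self


class OutputBlock(_Block):
    directory: str = "coralpump_out"


class RunConfig(_Block):
    """Validated top-level configuration for the full pipeline."""

    grid: GridBlock = GridBlock()
    bathymetry: BathymetryBlock = BathymetryBlock()
    forcing: ForcingBlock = ForcingBlock()
    habitat: HabitatBlock = HabitatBlock()
    om: OMBlock = OMBlock()
    scenario: ScenarioBlock = ScenarioBlock()
    output: OutputBlock = OutputBlock()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives the full defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig) -> str:
    return yaml.safe_dump(config.model_dump(), sort_keys=False)


# -- constructors from config blocks ----------------------------------------


def build_bathymetry(cfg: RunConfig) -> Bathymetry:
    b = cfg.bathymetry
    if b.mounds is None and b.ridge is None and b.slope_break is None:
        return synthflow.default_bathymetry(nx=b.nx, ny=b.ny, dx=b.dx, dy=b.dy)
    mounds = [((m.x, m.y), m.relief, m.radius) for m in (b.mounds or [])]
    ridge = (cfg.bathymetry.ridge.x, cfg.bathymetry.ridge.crest_depth,
             cfg.bathymetry.ridge.width) if b.ridge else None
    return synthflow.make_bathymetry(
        nx=b.nx, ny=b.ny, dx=b.dx, dy=b.dy,
        shelf_depth=b.shelf_depth, trough_depth=b.trough_depth,
        slope_break=b.slope_break, slope_width=b.slope_width,
        mound_spec=mounds, ridge_spec=ridge,
    )


def build_sigma_grid(cfg: RunConfig, bathymetry: Bathymetry) -> SigmaGrid:
    g = cfg.grid
    return build_grid(bathymetry, g.n_levels, g.theta_s, g.theta_b)


def build_forcing(cfg: RunConfig) -> TidalForcing:
    f = cfg.forcing
    return TidalForcing(
        u_amplitude=f.u_amplitude,
        tidal_period=f.tidal_period,
        springneap_period=f.springneap_period,
        modulation=f.modulation,
        direction=f.direction,
        reference_depth=f.reference_depth,
        surface_intensification=f.surface_intensification,
        intensification_scale=f.intensification_scale,
        transport_scaling=f.transport_scaling,
        background_transport=f.background_transport,
    )


def build_habitat(cfg: RunConfig, bathymetry: Bathymetry) -> HabitatMask:
    h = cfg.habitat
    return synthflow.make_habitat_mask(
        bathymetry,
        summit_window=tuple(h.summit_window),
        slope_threshold=h.slope_threshold,
        ridge_window=tuple(h.ridge_window),
        coverage=h.coverage,
    )


def build_om_params(cfg: RunConfig) -> OMParams:
    o = cfg.om
    return OMParams(ws=o.ws, k_decay=o.k_decay, surface_flux=o.surface_flux,
                    enhancement=o.enhancement)


def build_scenario(cfg: RunConfig, **overrides) -> ScenarioConfig:
    s = cfg.scenario.model_dump()
    s.update(overrides)
    return ScenarioConfig(**s)
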