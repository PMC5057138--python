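"""Run-record persistence: NetCDF fields, CSV mass-budget ledger, metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import SigmaGrid, grid_to_dataset, load_grid
from .omreaction import OMParams, RunRecord, ScenarioConfig
from .synthflow import HabitatMask, load_habitat_mask, save_habitat_mask
from .transport import TracerState

__all__ = ["save_run_record", "load_run_record"]


def save_run_record(run: RunRecord, directory: str | Path) -> Path:
    """Persist a finished run: fields to NetCDF, budget to CSV, params to JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    ds = grid_to_dataset(run.grid)
    ds["concentration"] = (
        ("layer", "y", "x"),
        run.final_state.concentration,
        {"units": "mmol C m-3", "time_days": run.final_state.time},
    )
    ds["deposition_flux"] = (
        ("y", "x"),
        run.deposition_flux,
        {"units": "mmol C m-2 d-1", "averaging_days": run.averaging_days},
    )
    ds["deposition_mass"] = (("y", "x"), run.deposition_mass, {"units": "mmol C"})
    ds.attrs["surface_w_residual"] = run.surface_w_residual
    ds.to_netcdf(directory / "run.nc", engine="scipy")

    save_habitat_mask(run.mask, directory / "habitat.nc")
    run.budget.to_csv(directory / "budget.csv", index=False)

    meta = {
        "params": vars(run.params) | {"ws_coral": run.params.ws_coral},
        "config": vars(run.config),
        "averaging_days": run.averaging_days,
    }
    (directory / "run.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_run_record(directory: str | Path) -> RunRecord:
    directory = Path(directory)
    grid = load_grid(directory / "run.nc")
    with xr.open_dataset(directory / "run.nc", engine="scipy") as ds:
        ds.load()
    mask = load_habitat_mask(directory / "habitat.nc")
    budget = pd.read_csv(directory / "budget.csv")
    meta = json.loads((directory / "run.json").read_text())
    params = OMParams(**{k: v for k, v in meta["params"].items() if k != "ws_coral"})
    config = ScenarioConfig(**meta["config"])
    return RunRecord(
        grid=grid,
        mask=mask,
        params=params,
        config=config,
        final_state=TracerState(
            concentration=ds["concentration"].values,
            time=float(ds["concentration"].attrs["time_days"]),
        ),
        deposition_flux=ds["deposition_flux"].values,
        deposition_mass=ds["deposition_mass"].values,
        averaging_days=float(meta["averaging_days"]),
        budget=budget,
        surface_w_residual=float(ds.attrs["surface_w_residual"]),
    )
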