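"""Result analyses: velocity extrema, transect sections, deposition focusing.

These mirror the standard diagnostics for topographically-enhanced carbon
pumping onto cold-water-coral habitat:

* time series of the strongest up- and downwelling over a region;
* vertical sections of any 3-D field along a transect, with the sigma
  coordinate unrolled to true depth;
* per-column time-mean deposition flux joined with depth and habitat class,
  binned by depth, with the coral / off-reef "focusing" ratio;
* a three-way scenario comparison (baseline, no filtration, no
  hydrodynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import SigmaGrid
from .omreaction import RunRecord
from .synthflow import FlowSeries, HabitatMask
from .transport import diagnose_w

__all__ = [
    "VelocityExtrema",
    "velocity_extrema",
    "transect_section",
    "deposition_vs_depth",
    "focusing_factor",
    "scenario_compare",
]

CORAL_CLASSES = ("coral_mound", "coral_ridge")


@dataclass(frozen=True)
class VelocityExtrema:
    """Per-snapshot maximum up- and downwelling speed over a region (m/s)."""

    times: np.ndarray
    max_upwelling: np.ndarray
    max_downwelling: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "max_upwelling": self.max_upwelling,
                "max_downwelling": self.max_downwelling,
            }
        )


def velocity_extrema(
    grid: SigmaGrid, flows: FlowSeries, region: np.ndarray
) -> VelocityExtrema:
    """Strongest simultaneous up- and downwelling over ``region`` columns.

    ``region`` is a boolean (ny, nx) mask; both outputs are non-negative
    magnitudes, reported at the flow-snapshot cadence.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != grid.bathymetry.shape:
        raise ValueError("region mask shape does not match grid")
    if not region.any():
        raise ValueError("region mask is empty")
    up, down, times = [], [], []
    for snap in flows:
        w = diagnose_w(grid, snap).w[:, region]
        up.append(max(float(w.max()), 0.0))
        down.append(max(float(-w.min()), 0.0))
        times.append(snap.time)
    return VelocityExtrema(
        times=np.array(times),
        max_upwelling=np.array(up),
        max_downwelling=np.array(down),
    )


def transect_section(
    grid: SigmaGrid, field: np.ndarray, j: int | None = None, i: int | None = None
) -> pd.DataFrame:
    """Extract a vertical section of a cell-centred 3-D field.

    Exactly one of ``j`` (along-x section) or ``i`` (along-y section) must be
    given.  Returns a tidy frame with columns ``distance`` (m along the
    transect), ``depth`` (true metres, from the sigma geometry), ``value``
    and ``seafloor`` (local bathymetry).
    """
    if (j is None) == (i is None):
        raise ValueError("specify exactly one of j (row) or i (column)")
    nz, ny, nx = grid.shape
    if field.shape != (nz, ny, nx):
        raise ValueError("field shape does not match grid")
    z = grid.depth_centers()
    b = grid.bathymetry
    if j is not None:
        if not 0 <= j < ny:
            raise ValueError(f"transect row j={j} outside domain")
        vals, depths = field[:, j, :], z[:, j, :]
        dist, floor = b.x, b.depth[j, :]
    else:
        if not 0 <= i < nx:
            raise ValueError(f"transect column i={i} outside domain")
        vals, depths = field[:, :, i], z[:, :, i]
        dist, floor = b.y, b.depth[:, i]
    n = vals.shape[1]
    return pd.DataFrame(
        {
            "distance": np.tile(dist, nz),
            "depth": depths.ravel(),
            "value": vals.ravel(),
            "seafloor": np.tile(floor, nz),
        }
    )


def deposition_vs_depth(
    run: RunRecord, mask: HabitatMask | None = None, bin_width: float = 100.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-column deposition table and binned coral / off-reef summary.

    Returns ``(table, summary)``: the table has one row per column with
    ``depth``, ``habitat_class`` and the post-spinup time-mean deposition
    flux (mmol C m-2 d-1); the summary has one row per ``bin_width``-metre
    depth bin with the mean coral and off-reef fluxes and their ratio
    (NaN where a bin lacks one of the classes).
    """
    if run.averaging_days <= 0:
        raise ValueError("run has no post-spinup samples to average")
    mask = mask or run.mask
    depth = run.grid.bathymetry.depth
    table = pd.DataFrame(
        {
            "depth": depth.ravel(),
            "habitat_class": mask.habitat_class.ravel(),
            "deposition": run.deposition_flux.ravel(),
        }
    )
    table["coral"] = table["habitat_class"].isin(CORAL_CLASSES)
    table["depth_bin"] = (table["depth"] // bin_width).astype(int) * bin_width

    grouped = table.groupby(["depth_bin", "coral"])["deposition"].mean().unstack()
    summary = pd.DataFrame(index=grouped.index)
    summary["off_reef_mean"] = grouped.get(False, np.nan)
    summary["coral_mean"] = grouped.get(True, np.nan)
    summary["ratio"] = summary["coral_mean"] / summary["off_reef_mean"]
    summary["n_coral"] = table[table["coral"]].groupby("depth_bin").size()
    summary["n_off_reef"] = table[~table["coral"]].groupby("depth_bin").size()
    summary = summary.reset_index().fillna({"n_coral": 0, "n_off_reef": 0})
    return table, summary


def focusing_factor(run: RunRecord, bin_width: float = 100.0) -> float:
    """Mean coral / off-reef deposition ratio over matched depth bins.

    Only bins containing both habitat classes contribute ("at similar water
    depth"); the ratio of bin means is averaged across those bins.
    """
    _, summary = deposition_vs_depth(run, bin_width=bin_width)
    matched = summary.dropna(subset=["ratio"])
    matched = matched[(matched["n_coral"] > 0) & (matched["n_off_reef"] > 0)]
    if matched.empty:
        raise ValueError("no depth bin contains both coral and off-reef columns")
    return float(matched["ratio"].mean())


def scenario_compare(
    baseline: RunRecord,
    no_filtration: RunRecord,
    no_hydro: RunRecord,
    bin_width: float = 100.0,
) -> pd.DataFrame:
    """Three-way scenario comparison per depth bin and habitat class.

    Returns one row per (depth bin, habitat class) with the time-mean
    deposition flux of each scenario and the ratios baseline / no_hydro and
    baseline / no_filtration.
    """
    runs = {"baseline": baseline, "no_filtration": no_filtration, "no_hydro": no_hydro}
    shapes = {k: r.grid.bathymetry.shape for k, r in runs.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"runs are on different grids: {shapes}")
    if not all(
        np.array_equal(r.mask.coral, baseline.mask.coral) for r in runs.values()
    ):
        raise ValueError("runs use different habitat masks")

    frames = []
    for name, run in runs.items():
        tab, _ = deposition_vs_depth(run, bin_width=bin_width)
        g = tab.groupby(["depth_bin", "habitat_class"])["deposition"].mean()
        frames.append(g.rename(name))
    out = pd.concat(frames, axis=1).reset_index()
    out["baseline_over_no_hydro"] = out["baseline"] / out["no_hydro"]
    out["baseline_over_no_filtration"] = out["baseline"] / out["no_filtration"]
    return out
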