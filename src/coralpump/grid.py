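"""Terrain-following (sigma) grids over arbitrary bathymetry.

The vertical coordinate follows the seafloor: every water column is divided
into the same number of layers, whose thicknesses ``Hz`` scale with the local
water depth ``H``.  Horizontally the grid is a rectilinear Arakawa C-grid:
scalars live at cell centres, the ``u`` velocity on x-faces, ``v`` on y-faces
and the vertical velocity ``w`` on the horizontal interfaces between layers.

Conventions
-----------
* depths are positive-down, in metres;
* the layer index ``k = 0`` is the *bottom* layer, increasing upward;
* sigma runs from -1 (seafloor) to 0 (surface); the free surface is rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "Bathymetry",
    "SigmaGrid",
    "build_sigma_levels",
    "build_grid",
    "save_grid",
    "load_grid",
]


@dataclass(frozen=True)
class Bathymetry:
    """Positive water depth ``H(y, x)`` on a rectilinear grid.

    Parameters
    ----------
    depth : ndarray, shape (ny, nx)
        Water depth in metres, strictly positive.
    dx, dy : float
        Horizontal cell sizes in metres.
    x, y : ndarray
        Cell-centre coordinates in metres.
    """

    depth: np.ndarray
    dx: float
    dy: float
    x: np.ndarray = None
    y: np.ndarray = None

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        if depth.ndim != 2:
            raise ValueError("depth must be 2-D (ny, nx)")
        if not np.all(np.isfinite(depth)) or np.any(depth <= 0):
            raise ValueError("depth must be finite and strictly positive")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx and dy must be positive")
        object.__setattr__(self, "depth", depth)
        ny, nx = depth.shape
        x = self.x if self.x is not None else (np.arange(nx) + 0.5) * self.dx
        y = self.y if self.y is not None else (np.arange(ny) + 0.5) * self.dy
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.shape != (nx,) or y.shape != (ny,):
            raise ValueError("coordinate vectors inconsistent with depth shape")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


def _stretching(sigma: np.ndarray, theta_s: float, theta_b: float) -> np.ndarray:
    """Monotone stretching C(sigma) on [-1, 0] (Song & Haidvogel 1994 form).

    theta_s > 0 concentrates resolution at the boundaries; theta_b in [0, 1]
    shifts refinement toward the bottom (theta_b = 1 refines both surface and
    bottom symmetrically through the tanh term).  theta_s = 0 is the identity.
    """
    if theta_s == 0:
        return sigma.copy()
    c = (1.0 - theta_b) * np.sinh(theta_s * sigma) / np.sinh(theta_s)
    c += theta_b * (
        np.tanh(theta_s * (sigma + 0.5)) / (2.0 * np.tanh(0.5 * theta_s)) - 0.5
    )
    return c


def build_sigma_levels(
    n_levels: int, theta_s: float = 3.4, theta_b: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Build sigma centre and interface coordinates for ``n_levels`` layers.

    Returns
    -------
    sigma_centers : ndarray, shape (n_levels,)
        Layer-centre sigma values, bottom first.
    sigma_interfaces : ndarray, shape (n_levels + 1,)
        Interface sigma values, strictly increasing from -1 to 0.
    """
    if not isinstance(n_levels, (int, np.integer)) or n_levels < 2:
        raise ValueError(f"n_levels must be an integer >= 2, got {n_levels!r}")
    if theta_s < 0:
        raise ValueError(f"theta_s must be non-negative, got {theta_s}")
    if not 0.0 <= theta_b <= 1.0:
        raise ValueError(f"theta_b must lie in [0, 1], got {theta_b}")
    s_w = np.linspace(-1.0, 0.0, n_levels + 1)
    s_r = (s_w[:-1] + s_w[1:]) / 2.0
    interfaces = _stretching(s_w, theta_s, theta_b)
    centers = _stretching(s_r, theta_s, theta_b)
    # exact endpoints regardless of round-off
    interfaces[0], interfaces[-1] = -1.0, 0.0
    if np.any(np.diff(interfaces) <= 0):
        raise ValueError("stretching produced non-monotone interfaces")
    return centers, interfaces


@dataclass(frozen=True)
class SigmaGrid:
    """Terrain-following grid with per-cell layer thicknesses.

    ``Hz[k, j, i]`` is the thickness (m) of layer ``k`` in column ``(j, i)``;
    the sum of ``Hz`` over ``k`` reproduces the local water depth exactly.
    """

    bathymetry: Bathymetry
    n_levels: int
    sigma_centers: np.ndarray
    sigma_interfaces: np.ndarray
    theta_s: float
    theta_b: float
    Hz: np.ndarray
    wet: np.ndarray = None  # mask hook; all-wet by default

    def __post_init__(self) -> None:
        if self.wet is None:
            object.__setattr__(
                self, "wet", np.ones(self.bathymetry.shape, dtype=bool)
            )

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        ny, nx = self.bathymetry.shape
        return (self.n_levels, ny, nx)

    @property
    def dx(self) -> float:
        return self.bathymetry.dx

    @property
    def dy(self) -> float:
        return self.bathymetry.dy

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def cell_volume(self) -> np.ndarray:
        """Cell volumes in m^3, shape (nz, ny, nx)."""
        return self.Hz * self.cell_area

    def depth_interfaces(self) -> np.ndarray:
        """Positive-down depth of layer interfaces, shape (nz+1, ny, nx)."""
        return -self.sigma_interfaces[:, None, None] * self.bathymetry.depth[None]

    def depth_centers(self) -> np.ndarray:
        """Positive-down depth of layer centres, shape (nz, ny, nx)."""
        return -self.sigma_centers[:, None, None] * self.bathymetry.depth[None]

    def hz_u(self) -> np.ndarray:
        """Layer thickness at u-faces (nz, ny, nx+1); edges copy the interior."""
        Hz = self.Hz
        out = np.empty((self.n_levels, Hz.shape[1], Hz.shape[2] + 1))
        out[:, :, 1:-1] = 0.5 * (Hz[:, :, :-1] + Hz[:, :, 1:])
        out[:, :, 0] = Hz[:, :, 0]
        out[:, :, -1] = Hz[:, :, -1]
        return out

    def hz_v(self) -> np.ndarray:
        """Layer thickness at v-faces (nz, ny+1, nx); edges copy the interior."""
        Hz = self.Hz
        out = np.empty((self.n_levels, Hz.shape[1] + 1, Hz.shape[2]))
        out[:, 1:-1, :] = 0.5 * (Hz[:, :-1, :] + Hz[:, 1:, :])
        out[:, 0, :] = Hz[:, 0, :]
        out[:, -1, :] = Hz[:, -1, :]
        return out


def build_grid(
    bathymetry: Bathymetry,
    n_levels: int = 32,
    theta_s: float = 3.4,
    theta_b: float = 1.0,
) -> SigmaGrid:
    """Build a :class:`SigmaGrid` over ``bathymetry``.

    Layer thicknesses are ``Hz[k] = H * (sigma_int[k+1] - sigma_int[k])`` so
    column sums of ``Hz`` reproduce ``H`` by construction.
    """
    centers, interfaces = build_sigma_levels(n_levels, theta_s, theta_b)
    dsigma = np.diff(interfaces)  # (nz,), positive
    Hz = dsigma[:, None, None] * bathymetry.depth[None, :, :]
    return SigmaGrid(
        bathymetry=bathymetry,
        n_levels=int(n_levels),
        sigma_centers=centers,
        sigma_interfaces=interfaces,
        theta_s=float(theta_s),
        theta_b=float(theta_b),
        Hz=Hz,
    )


# -- NetCDF round-trip -------------------------------------------------------


def grid_to_dataset(grid: SigmaGrid) -> xr.Dataset:
    b = grid.bathymetry
    return xr.Dataset(
        data_vars={
            "depth": (("y", "x"), b.depth, {"units": "m", "positive": "down"}),
            "Hz": (("layer", "y", "x"), grid.Hz, {"units": "m"}),
            "sigma": (("layer",), grid.sigma_centers),
            "sigma_w": (("interface",), grid.sigma_interfaces),
        },
        coords={"x": b.x, "y": b.y},
        attrs={
            "dx": b.dx,
            "dy": b.dy,
            "n_levels": grid.n_levels,
            "theta_s": grid.theta_s,
            "theta_b": grid.theta_b,
        },
    )


def save_grid(grid: SigmaGrid, path: str | Path) -> None:
    grid_to_dataset(grid).to_netcdf(path, engine="scipy")


def load_grid(path: str | Path) -> SigmaGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    bathy = Bathymetry(
        depth=ds["depth"].values,
        dx=float(ds.attrs["dx"]),
        dy=float(ds.attrs["dy"]),
        x=ds["x"].values,
        y=ds["y"].values,
    )
    return SigmaGrid(
        bathymetry=bathy,
        n_levels=int(ds.attrs["n_levels"]),
        sigma_centers=ds["sigma"].values,
        sigma_interfaces=ds["sigma_w"].values,
        theta_s=float(ds.attrs["theta_s"]),
        theta_b=float(ds.attrs["theta_b"]),
        Hz=ds["Hz"].values,
    )


def transect_profile_csv(grid: SigmaGrid, j: int, path: str | Path) -> pd.DataFrame:
    """Export a 1-D along-x depth transect at row ``j`` as CSV."""
    b = grid.bathymetry
    df = pd.DataFrame({"x": b.x, "depth": b.depth[j, :]})
    df.to_csv(path, index=False)
    return df
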