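"""Synthetic inputs: mound/ridge bathymetry, tidal flow series, habitat mask.

This module emulates the three inputs the reaction-transport model needs:

* a shelf-slope bathymetry (shallow bank to deep trough) decorated with
  Gaussian carbonate mounds and a shelf-break ridge;
* a transport-conserving barotropic tidal flow, semidiurnal and modulated by
  a spring-neap envelope, stored as snapshots at a fixed cadence;
* a boolean cold-water-coral habitat mask on mound summits/flanks and the
  ridge crest (a geometric stand-in for a habitat-suitability model).

The flow is derived from a depth-integrated transport streamfunction, so the
depth-integrated horizontal transport is non-divergent to round-off: under a
rigid lid all diagnosed vertical motion then comes from topographic flux
divergence within the column, which is exactly the pumping mechanism of
interest.  There is no baroclinic (internal-wave) vertical structure and no
momentum dynamics of any kind.  Generators are seed-free: identical
configurations give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .grid import Bathymetry, SigmaGrid

__all__ = [
    "TidalForcing",
    "FlowSnapshot",
    "FlowSeries",
    "HabitatMask",
    "make_bathymetry",
    "make_habitat_mask",
    "make_tidal_flow",
    "save_flow_series",
    "load_flow_series",
    "save_habitat_mask",
    "load_habitat_mask",
]

MIN_DEPTH = 50.0  # m; generated bathymetry never shoals beyond this

HABITAT_CLASSES = ("off_reef", "coral_mound", "coral_ridge")


@dataclass(frozen=True)
class TidalForcing:
    """Barotropic tidal forcing parameters.

    ``u_amplitude`` is the peak depth-averaged speed (m/s) over seafloor at
    the local *background* depth (the along-flow median bathymetry).  With
    the default ``transport_scaling="background"`` the depth-integrated
    transport follows the background depth across the flow, so the
    depth-averaged speed is ``u_amplitude`` over smooth slope and amplified
    by ``H_background / H`` where mounds and ridges shoal the column —
    tidal acceleration over topography.  With ``transport_scaling=
    "constant"`` the transport is ``u_amplitude * reference_depth``
    everywhere and the speed scales as ``reference_depth / H``.  The default
    amplitude is calibrated so the time-mean near-bottom speed above the
    coral habitat is roughly 0.3 m/s.  The speed envelope is

        U0(t) = u_amplitude * (1 - modulation * cos(2 pi t / T_sn))
                            * cos(2 pi t / T_tide)

    with the semidiurnal period ``T_tide`` (hours) and the spring-neap
    envelope period ``T_sn`` (days).  ``direction`` is the flow azimuth in
    degrees anticlockwise from the +x axis.
    """

    u_amplitude: float = 0.4
    tidal_period: float = 12.42  # hours (M2)
    springneap_period: float = 14.77  # days (M2/S2 beat)
    modulation: float = 0.4
    direction: float = 0.0  # degrees from +x; default cross-isobath
    reference_depth: float = 600.0  # m; transport scale when not depth-local
    transport_scaling: str = "background"  # "background" or "constant"
    background_transport: float = 0.0  # m^2/s residual transport, optional
    surface_intensification: float = 1.0  # delta of the vertical profile
    intensification_scale: float = 300.0  # m; e-folding depth of the profile

    def __post_init__(self) -> None:
        if self.u_amplitude <= 0:
            raise ValueError("u_amplitude must be positive")
        if not 0.0 <= self.modulation < 1.0:
            raise ValueError("modulation must lie in [0, 1)")
        if self.tidal_period <= 0 or self.springneap_period <= 0:
            raise ValueError("periods must be positive")
        if self.reference_depth <= 0:
            raise ValueError("reference_depth must be positive")
        if self.surface_intensification < 0 or self.intensification_scale <= 0:
            raise ValueError("invalid vertical-structure parameters")

    def envelope(self, t_days) -> np.ndarray:
        """Depth-averaged speed U0(t) at the reference depth, in m/s."""
        t = np.asarray(t_days, dtype=float)
        sn = 1.0 - self.modulation * np.cos(2 * np.pi * t / self.springneap_period)
        return self.u_amplitude * sn * np.cos(2 * np.pi * t / (self.tidal_period / 24.0))


@dataclass(frozen=True)
class FlowSnapshot:
    """Horizontal velocity on C-grid faces at one instant.

    ``u`` has shape (nz, ny, nx+1) on x-faces, ``v`` (nz, ny+1, nx) on
    y-faces, both in m/s; ``time`` is in days.
    """

    u: np.ndarray
    v: np.ndarray
    time: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("velocity fields must be finite")


@dataclass
class FlowSeries:
    """Time-ordered sequence of :class:`FlowSnapshot`."""

    snapshots: list[FlowSnapshot]

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, i: int) -> FlowSnapshot:
        return self.snapshots[i]

    def __iter__(self):
        return iter(self.snapshots)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])


@dataclass(frozen=True)
class HabitatMask:
    """Per-column coral presence and habitat class.

    ``coral`` is boolean (ny, nx); ``habitat_class`` holds one of
    ``off_reef``, ``coral_mound``, ``coral_ridge`` per column.
    """

    coral: np.ndarray
    habitat_class: np.ndarray

    def __post_init__(self) -> None:
        coral = np.asarray(self.coral, dtype=bool)
        cls = np.asarray(self.habitat_class)
        if coral.shape != cls.shape:
            raise ValueError("coral and habitat_class shapes differ")
        if np.any(coral & (cls == "off_reef")):
            raise ValueError("coral columns must carry a coral habitat class")
        object.__setattr__(self, "coral", coral)
        object.__setattr__(self, "habitat_class", cls)


# ---------------------------------------------------------------------------
# bathymetry


def _slope_profile(x: np.ndarray, shelf_depth: float, trough_depth: float,
                   break_pos: float, slope_width: float) -> np.ndarray:
    """Smooth tanh shelf-to-trough depth profile along x."""
    mid = 0.5 * (shelf_depth + trough_depth)
    half = 0.5 * (trough_depth - shelf_depth)
    return mid + half * np.tanh((x - break_pos) / slope_width)


def make_bathymetry(
    nx: int = 60,
    ny: int = 40,
    dx: float = 250.0,
    dy: float = 250.0,
    shelf_depth: float = 200.0,
    trough_depth: float = 2000.0,
    slope_break: float | None = None,
    slope_width: float | None = None,
    mound_spec: list[tuple[tuple[float, float], float, float]] | None = None,
    ridge_spec: tuple[float, float, float] | None = None,
) -> Bathymetry:
    """Build a shelf-slope bathymetry with Gaussian mounds and a ridge.

    The base profile is a tanh slope from ``shelf_depth`` (low x) down to
    ``trough_depth`` (high x).  Each mound is ``((x0, y0), relief, radius)``
    in metres and is *subtracted* from the local depth as a Gaussian bump.
    The ridge is ``(x_position, crest_depth, width)``: a Gaussian ridge
    running along y whose crest is raised to ``crest_depth``.

    Raises a ``ValueError`` if a mound's relief reaches the local depth.
    """
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    if slope_break is None:
        slope_break = 0.5 * nx * dx
    if slope_width is None:
        slope_width = 0.18 * nx * dx
    depth = np.broadcast_to(
        _slope_profile(x, shelf_depth, trough_depth, slope_break, slope_width),
        (ny, nx),
    ).copy()

    xx, yy = np.meshgrid(x, y)
    for (x0, y0), relief, radius in mound_spec or []:
        ix = int(np.clip(round(x0 / dx - 0.5), 0, nx - 1))
        iy = int(np.clip(round(y0 / dy - 0.5), 0, ny - 1))
        local = depth[iy, ix]
        if relief >= local:
            raise ValueError(
                f"mound relief {relief} m >= local depth {local:.0f} m at ({x0}, {y0})"
            )
        r2 = (xx - x0) ** 2 + (yy - y0) ** 2
        depth -= relief * np.exp(-r2 / (2.0 * radius**2))

    if ridge_spec is not None:
        x_pos, crest_depth, width = ridge_spec
        profile_at_crest = _slope_profile(
            np.array([x_pos]), shelf_depth, trough_depth, slope_break, slope_width
        )[0]
        relief = profile_at_crest - crest_depth
        if relief >= profile_at_crest:
            raise ValueError("ridge crest depth must be positive")
        if relief > 0:
            depth -= relief * np.exp(-((xx - x_pos) ** 2) / (2.0 * width**2))

    depth = np.maximum(depth, MIN_DEPTH)
    return Bathymetry(depth=depth, dx=dx, dy=dy, x=x, y=y)


def default_bathymetry(nx: int = 60, ny: int = 40, dx: float = 250.0,
                       dy: float = 250.0) -> Bathymetry:
    """Study-condition bathymetry: 200-2000 m slope, one 380-m mound whose
    summit sits at 600 m, and a shelf-break ridge cresting at 450 m."""
    Lx, Ly = nx * dx, ny * dy
    slope_break = 0.5 * Lx
    slope_width = 0.25 * Lx  # wide enough to separate ridge and mound
    # place the mound where the background slope is 980 m so the summit is 600 m
    x_m = _invert_slope(980.0, 200.0, 2000.0, slope_break, slope_width)
    ridge_x = _invert_slope(500.0, 200.0, 2000.0, slope_break, slope_width)
    return make_bathymetry(
        nx=nx, ny=ny, dx=dx, dy=dy,
        shelf_depth=200.0, trough_depth=2000.0,
        slope_break=slope_break, slope_width=slope_width,
        mound_spec=[((x_m, 0.5 * Ly), 380.0, 900.0)],
        ridge_spec=(ridge_x, 450.0, 700.0),
    )


def _invert_slope(target_depth: float, shelf: float, trough: float,
                  break_pos: float, width: float) -> float:
    frac = (target_depth - 0.5 * (shelf + trough)) / (0.5 * (trough - shelf))
    return break_pos + width * np.arctanh(frac)


# ---------------------------------------------------------------------------
# habitat mask


def _spatial_hash(ny: int, nx: int) -> np.ndarray:
    """Deterministic quasi-random field in [0, 1) per column (seed-free)."""
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    h = (ii * 2654435761 + jj * 40503 + 12345) & 0xFFFFFFFF
    h ^= h >> 16
    h = (h * 2246822519) & 0xFFFFFFFF
    h ^= h >> 13
    return (h & 0xFFFF) / 65536.0


def make_habitat_mask(
    bathymetry: Bathymetry,
    summit_window: tuple[float, float] = (400.0, 1000.0),
    slope_threshold: float = 20.0,
    ridge_window: tuple[float, float] = (400.0, 550.0),
    coverage: float = 0.4,
) -> HabitatMask:
    """Geometric coral-habitat stand-in: depth window plus positive relief.

    A column is *eligible* coral habitat when its depth lies inside
    ``summit_window`` *and* it stands proud of the background along-y depth
    (local relief above the y-median of its row of constant x exceeds
    ``slope_threshold`` metres).  Relief features inside ``ridge_window``
    depths are classed ``coral_ridge`` (the shelf-break ridge), deeper ones
    ``coral_mound``.

    ``coverage`` is the fraction of eligible columns that actually host
    coral, thinned by a deterministic spatial hash.  This emulates habitat
    predictions being scattered presence points on summits and flanks rather
    than a closed blanket; ``coverage = 1`` marks every eligible column.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    depth = bathymetry.depth
    background = np.median(depth, axis=0, keepdims=True)  # along-y background
    relief = background - depth  # positive where the column stands proud
    lo, hi = summit_window
    in_window = (depth >= lo) & (depth <= hi)
    coral = in_window & (relief > slope_threshold)
    if coverage < 1.0:
        coral &= _spatial_hash(*depth.shape) < coverage

    cls = np.full(depth.shape, "off_reef", dtype=object)
    on_ridge = coral & (depth >= ridge_window[0]) & (depth <= ridge_window[1]) & (
        np.broadcast_to(background, depth.shape) <= ridge_window[1] + 200.0
    )
    cls[coral] = "coral_mound"
    cls[on_ridge] = "coral_ridge"

    if not coral.any():
        warnings.warn(
            "habitat mask is empty: filtration will have no effect", stacklevel=2
        )
    return HabitatMask(coral=coral, habitat_class=cls.astype("U11"))


# ---------------------------------------------------------------------------
# tidal flow


def make_tidal_flow(
    grid: SigmaGrid,
    forcing: TidalForcing,
    t_start: float,
    t_end: float,
    cadence: float = 6.0,
) -> FlowSeries:
    """Generate a transport-conserving tidal flow series at fixed cadence.

    ``cadence`` is in hours.  The depth-integrated transport at each instant
    derives from a streamfunction on grid nodes, so its discrete divergence is
    zero per column to round-off and the diagnosed surface (rigid-lid)
    vertical velocity vanishes.

    The vertical structure of the velocity follows a surface-intensified
    profile ``phi(z) = 1 + delta * exp(-z / z_scale)`` (z positive down),
    normalised per face so the depth-integrated transport is unchanged.  A
    profile that depends on true depth is essential: a vertically uniform
    current on a terrain-following grid assigns every layer a fixed fraction
    of the (non-divergent) transport, so no layer ever diverges and there is
    no topographic up/downwelling at all.  ``delta = 0`` recovers the uniform
    profile.
    """
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")

    b = grid.bathymetry
    ny, nx = b.shape
    nz = grid.n_levels
    dx, dy = b.dx, b.dy

    # streamfunction on nodes: psi depends only on the cross-flow coordinate
    # eta, so the depth-integrated transport is non-divergent by construction
    theta = np.deg2rad(forcing.direction)
    dxv, dyv = np.cos(theta), np.sin(theta)
    x_node = np.arange(nx + 1) * dx
    y_node = np.arange(ny + 1) * dy
    xn, yn = np.meshgrid(x_node, y_node)  # (ny+1, nx+1)
    eta_node = dxv * yn - dyv * xn  # cross-flow coordinate, m
    if forcing.transport_scaling == "constant":
        # psi = H_ref * eta: uniform transport u_amplitude * reference_depth
        psi_unit = forcing.reference_depth * eta_node
    elif forcing.transport_scaling == "background":
        # psi' (eta) = background depth at that streamline, taken as the
        # along-flow median of the bathymetry: depth-averaged speed is the
        # envelope over smooth slope, amplified over mounds
        xc, yc = np.meshgrid(b.x, b.y)
        eta_c = (dxv * yc - dyv * xc).ravel()
        h = min(dx, dy)
        bins = np.round(eta_c / h).astype(int)
        order = np.argsort(bins, kind="stable")
        uniq, starts = np.unique(bins[order], return_index=True)
        med = np.array(
            [np.median(b.depth.ravel()[order][s:e]) for s, e in
             zip(starts, np.append(starts[1:], len(order)))]
        )
        eta_grid = uniq * h
        # integrate H_bg over eta to get the streamfunction profile
        g = np.concatenate([[0.0], np.cumsum(0.5 * (med[1:] + med[:-1])
                                             * np.diff(eta_grid))])
        psi_unit = np.interp(
            eta_node, eta_grid, g,
            left=g[0] + med[0] * 0.0, right=g[-1],
        )
        # linear extrapolation beyond the sampled eta range
        below = eta_node < eta_grid[0]
        above = eta_node > eta_grid[-1]
        psi_unit = np.where(below, g[0] + med[0] * (eta_node - eta_grid[0]),
                            psi_unit)
        psi_unit = np.where(above, g[-1] + med[-1] * (eta_node - eta_grid[-1]),
                            psi_unit)
    else:
        raise ValueError(
            f"unknown transport_scaling {forcing.transport_scaling!r}"
        )

    # face transports for unit depth-integrated transport (m^3/s per m^2/s)
    U_unit = psi_unit[1:, :] - psi_unit[:-1, :]  # (ny, nx+1) through x-faces
    V_unit = -(psi_unit[:, 1:] - psi_unit[:, :-1])  # (ny+1, nx) through y-faces

    hz_u = grid.hz_u()  # (nz, ny, nx+1)
    hz_v = grid.hz_v()

    def _profile_weights(hz: np.ndarray) -> np.ndarray:
        """phi(z)*hz per layer, normalised so layer weights sum to 1."""
        cum = np.cumsum(hz, axis=0)
        H = cum[-1]
        z_center = H[None] - (cum - 0.5 * hz)  # depth below surface
        phi = 1.0 + forcing.surface_intensification * np.exp(
            -z_center / forcing.intensification_scale
        )
        weights = phi * hz
        return weights / weights.sum(axis=0, keepdims=True)

    # velocity per unit transport: face transport distributed over layers by
    # the profile weights, then divided by the face cross-section
    u_unit = U_unit[None] * _profile_weights(hz_u) / (dy * hz_u)
    v_unit = V_unit[None] * _profile_weights(hz_v) / (dx * hz_v)

    dt = cadence / 24.0
    n = int(np.ceil((t_end - t_start) / dt - 1e-9)) + 1  # last snap >= t_end
    times = t_start + dt * np.arange(n)

    snapshots = []
    u_resid = forcing.background_transport / forcing.reference_depth
    for t in times:
        speed = forcing.envelope(t) + u_resid
        snapshots.append(
            FlowSnapshot(u=speed * u_unit, v=speed * v_unit, time=float(t))
        )
    return FlowSeries(snapshots)


# ---------------------------------------------------------------------------
# NetCDF round-trips


def save_flow_series(series: FlowSeries, path: str | Path) -> None:
    u = np.stack([s.u for s in series])
    v = np.stack([s.v for s in series])
    ds = xr.Dataset(
        data_vars={
            "u": (("time", "layer", "y", "x_face"), u, {"units": "m s-1"}),
            "v": (("time", "layer", "y_face", "x"), v, {"units": "m s-1"}),
        },
        coords={"time": ("time", series.times, {"units": "days"})},
    )
    ds.to_netcdf(path, engine="scipy")


def load_flow_series(path: str | Path) -> FlowSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    snaps = [
        FlowSnapshot(
            u=ds["u"].values[i], v=ds["v"].values[i], time=float(ds["time"].values[i])
        )
        for i in range(ds.sizes["time"])
    ]
    return FlowSeries(snaps)


def save_habitat_mask(mask: HabitatMask, path: str | Path) -> None:
    class_code = np.array(
        [[HABITAT_CLASSES.index(c) for c in row] for row in mask.habitat_class]
    )
    ds = xr.Dataset(
        data_vars={
            "coral": (("y", "x"), mask.coral.astype(np.int8)),
            "habitat_code": (("y", "x"), class_code.astype(np.int8)),
        },
        attrs={"habitat_classes": ",".join(HABITAT_CLASSES)},
    )
    ds.to_netcdf(path, engine="scipy")


def load_habitat_mask(path: str | Path) -> HabitatMask:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    classes = np.array(HABITAT_CLASSES)
    return HabitatMask(
        coral=ds["coral"].values.astype(bool),
        habitat_class=classes[ds["habitat_code"].values.astype(int)],
    )
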