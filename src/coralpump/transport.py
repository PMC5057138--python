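"""Vertical-velocity diagnosis and mass-conservative upwind advection.

The tracer lives at cell centres; horizontal velocities on C-grid faces.
Vertical velocity is not prognostic: it is diagnosed per column from the
flux divergence of the horizontal flows under a rigid lid, integrating
upward from a no-flow bottom boundary.  Advection is first-order upwind
(donor cell) in flux form, so interior tracer mass changes only through
boundary fluxes; the numerical dispersion of the scheme stands in for
explicit diffusion, of which there is none.

Units: velocities in m/s, time steps in days (converted internally),
concentrations in mmol C m-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SigmaGrid
from .synthflow import FlowSeries, FlowSnapshot

__all__ = [
    "WField",
    "TracerState",
    "StepFluxes",
    "diagnose_w",
    "interp_flow",
    "advect_upwind",
    "cfl_max_dt",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class WField:
    """Vertical velocity on layer interfaces, (nz+1, ny, nx) in m/s.

    ``w[0]`` is the bottom interface (exactly zero); ``w[-1]`` the surface,
    whose magnitude — the rigid-lid residual — is kept as a diagnostic.
    """

    w: np.ndarray
    surface_residual: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.w)):
            raise ValueError("w must be finite")
        if np.any(self.w[0] != 0.0):
            raise ValueError("bottom-interface w must be exactly zero")


@dataclass
class TracerState:
    """Cell-centred organic-carbon concentration (mmol C m-3) at one time."""

    concentration: np.ndarray
    time: float

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValueError("concentration must be finite")
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        self.concentration = c


@dataclass(frozen=True)
class StepFluxes:
    """Mass bookkeeping of one advection step (mmol C).

    ``deposition`` is the per-column mass through the bottom face (>= 0);
    ``lateral_export`` the net outward mass through the four lateral walls
    and the (residual) surface face.
    """

    deposition: np.ndarray
    lateral_export: float


def _face_fluxes(grid: SigmaGrid, snapshot: FlowSnapshot):
    """Per-layer volume fluxes through u- and v-faces, m^3/s."""
    Fu = snapshot.u * grid.hz_u() * grid.dy
    Fv = snapshot.v * grid.hz_v() * grid.dx
    return Fu, Fv


def diagnose_w(grid: SigmaGrid, snapshot: FlowSnapshot) -> WField:
    """Diagnose the vertical velocity from horizontal flux divergence.

    Integrating the continuity equation upward from the bottom (where the
    vertical velocity vanishes), the volume flux through interface ``k+1``
    equals that through interface ``k`` minus the net horizontal volume flux
    divergence of layer ``k``.  The rigid-lid residual at the surface is
    reported, not forced to zero.
    """
    nz, ny, nx = grid.shape
    if snapshot.u.shape != (nz, ny, nx + 1) or snapshot.v.shape != (nz, ny + 1, nx):
        raise ValueError(
            f"snapshot shapes {snapshot.u.shape}/{snapshot.v.shape} do not match "
            f"grid {grid.shape}"
        )
    Fu, Fv = _face_fluxes(grid, snapshot)
    div = (Fu[:, :, 1:] - Fu[:, :, :-1]) + (Fv[:, 1:, :] - Fv[:, :-1, :])
    Fw = np.zeros((nz + 1, ny, nx))
    np.cumsum(-div, axis=0, out=Fw[1:])
    w = Fw / grid.cell_area
    return WField(w=w, surface_residual=float(np.max(np.abs(w[-1]))))


def interp_flow(series: FlowSeries, t: float) -> FlowSnapshot:
    """Linearly interpolate the flow series to time ``t`` (days)."""
    times = series.times
    if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
        raise ValueError(f"t={t} outside flow series span [{times[0]}, {times[-1]}]")
    i = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2))
    s0, s1 = series[i], series[i + 1]
    frac = (t - s0.time) / (s1.time - s0.time)
    frac = min(max(frac, 0.0), 1.0)
    if frac == 0.0:
        return FlowSnapshot(u=s0.u, v=s0.v, time=float(t))
    if frac == 1.0:
        return FlowSnapshot(u=s1.u, v=s1.v, time=float(t))
    return FlowSnapshot(
        u=(1 - frac) * s0.u + frac * s1.u,
        v=(1 - frac) * s0.v + frac * s1.v,
        time=float(t),
    )


def advect_upwind(
    state: TracerState,
    grid: SigmaGrid,
    snapshot: FlowSnapshot,
    w_total: np.ndarray,
    dt: float,
    check_cfl: bool = True,
) -> tuple[TracerState, StepFluxes]:
    """One donor-cell advection step of length ``dt`` days.

    ``w_total`` is the vertical face velocity (m/s) on interfaces, including
    any settling contribution; its bottom entry is the (negative) effective
    settling velocity, whose flux is recorded as deposition rather than
    discarded.  Lateral and surface boundaries are zero-gradient: the ghost
    concentration equals the adjacent interior value, so outflow exports the
    boundary cell's tracer and inflow imports the same concentration.
    """
    nz, ny, nx = grid.shape
    C = state.concentration
    if C.shape != (nz, ny, nx):
        raise ValueError("tracer shape does not match grid")
    if check_cfl:
        dt_max = cfl_max_dt(grid, snapshot, w_total, safety=1.0, cap=np.inf)
        if dt > dt_max * (1 + 1e-12):
            raise ValueError(
                f"CFL violation: dt={dt:.3e} d exceeds donor-cell limit "
                f"{dt_max:.3e} d"
            )
    dts = dt * SECONDS_PER_DAY
    Fu, Fv = _face_fluxes(grid, snapshot)  # m^3/s

    # upwind (donor) concentrations on faces; zero-gradient ghosts mean the
    # boundary faces always use the adjacent interior cell.
    Cu = np.empty_like(Fu)
    Cu[:, :, 1:-1] = np.where(Fu[:, :, 1:-1] > 0, C[:, :, :-1], C[:, :, 1:])
    Cu[:, :, 0] = C[:, :, 0]
    Cu[:, :, -1] = C[:, :, -1]
    Cv = np.empty_like(Fv)
    Cv[:, 1:-1, :] = np.where(Fv[:, 1:-1, :] > 0, C[:, :-1, :], C[:, 1:, :])
    Cv[:, 0, :] = C[:, 0, :]
    Cv[:, -1, :] = C[:, -1, :]

    Fw = w_total * grid.cell_area  # m^3/s, positive up
    Cw = np.empty_like(Fw)
    Cw[1:-1] = np.where(Fw[1:-1] > 0, C[:-1], C[1:])
    Cw[0] = C[0]  # bottom face: donor is the bottom cell (settling out)
    Cw[-1] = C[-1]  # surface face: zero-gradient ghost above

    Mu = Fu * Cu * dts  # mmol C through each face over the step
    Mv = Fv * Cv * dts
    Mw = Fw * Cw * dts

    vol = grid.cell_volume
    dC = -(
        (Mu[:, :, 1:] - Mu[:, :, :-1])
        + (Mv[:, 1:, :] - Mv[:, :-1, :])
        + (Mw[1:] - Mw[:-1])
    ) / vol
    C_new = C + dC
    # clamp tiny negative round-off without touching real values
    np.maximum(C_new, 0.0, out=C_new, where=C_new > -1e-13 * max(C.max(), 1.0))

    deposition = -Mw[0]  # mmol C per column, >= 0 when settling downward
    lateral = (
        Mu[:, :, -1].sum() - Mu[:, :, 0].sum()
        + Mv[:, -1, :].sum() - Mv[:, 0, :].sum()
        + Mw[-1].sum()
    )
    return (
        TracerState(concentration=C_new, time=state.time + dt),
        StepFluxes(deposition=deposition, lateral_export=float(lateral)),
    )


def cfl_max_dt(
    grid: SigmaGrid,
    snapshot: FlowSnapshot,
    w_total: np.ndarray,
    ws_max: float = 0.0,
    safety: float = 0.8,
    cap: float = 0.05,
) -> float:
    """Largest stable step (days) for the donor-cell scheme.

    The binding constraint is the per-cell total-outflow Courant number:
    dt * (sum of outgoing volume fluxes) / cell volume <= ``safety``.  With a
    single active face this reduces to the familiar |u| dt / dx bound.
    ``ws_max`` (m/d, positive) adds an extra downward settling margin on all
    vertical faces when ``w_total`` does not already include it.  Zero flow
    returns ``cap``.
    """
    Fu, Fv = _face_fluxes(grid, snapshot)
    Fw = (w_total - ws_max / SECONDS_PER_DAY) * grid.cell_area
    out = (
        np.maximum(Fu[:, :, 1:], 0.0) + np.maximum(-Fu[:, :, :-1], 0.0)
        + np.maximum(Fv[:, 1:, :], 0.0) + np.maximum(-Fv[:, :-1, :], 0.0)
        + np.maximum(Fw[1:], 0.0) + np.maximum(-Fw[:-1], 0.0)
    )
    rate = out / grid.cell_volume  # 1/s
    rmax = float(rate.max())
    if rmax <= 0.0:
        return cap
    return min(cap, safety / (rmax * SECONDS_PER_DAY))
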