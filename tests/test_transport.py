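"""Transport kernel tests: w diagnosis, interpolation, donor-cell advection.

The donor-cell oracle below is an independent, loop-based reimplementation of
the upwind update used to validate the vectorised kernel.
"""

import numpy as np
import pytest

from coralpump import (
    Bathymetry,
    TidalForcing,
    TracerState,
    advect_upwind,
    build_grid,
    cfl_max_dt,
    diagnose_w,
    interp_flow,
    make_tidal_flow,
)
from coralpump.synthflow import FlowSeries, FlowSnapshot
from coralpump.transport import SECONDS_PER_DAY, _face_fluxes


def _snapshot(grid, u=None, v=None, t=0.0):
    nz, ny, nx = grid.shape
    return FlowSnapshot(
        u=np.zeros((nz, ny, nx + 1)) if u is None else u,
        v=np.zeros((nz, ny + 1, nx)) if v is None else v,
        time=t,
    )


def _random_grid(rng, nz=4, ny=3, nx=5):
    depth = rng.uniform(100.0, 1500.0, size=(ny, nx))
    b = Bathymetry(depth=depth, dx=250.0, dy=200.0)
    return build_grid(b, nz)


def donor_cell_oracle(grid, C, u, v, w, dt_days):
    """Loop-based donor-cell update, including deposition bookkeeping."""
    nz, ny, nx = C.shape
    dts = dt_days * SECONDS_PER_DAY
    hz_u, hz_v = grid.hz_u(), grid.hz_v()
    dx, dy, area = grid.dx, grid.dy, grid.cell_area
    dC = np.zeros_like(C)
    dep = np.zeros((ny, nx))

    def donor(vel, c_minus, c_plus):
        return c_minus if vel > 0 else c_plus

    for k in range(nz):
        for j in range(ny):
            for i in range(nx + 1):
                cm = C[k, j, max(i - 1, 0)]
                cp = C[k, j, min(i, nx - 1)]
                flux = u[k, j, i] * hz_u[k, j, i] * dy * donor(u[k, j, i], cm, cp) * dts
                if i > 0:
                    dC[k, j, i - 1] -= flux / (grid.Hz[k, j, i - 1] * area)
                if i < nx:
                    dC[k, j, i] += flux / (grid.Hz[k, j, i] * area)
    for k in range(nz):
        for j in range(ny + 1):
            for i in range(nx):
                cm = C[k, max(j - 1, 0), i]
                cp = C[k, min(j, ny - 1), i]
                flux = v[k, j, i] * hz_v[k, j, i] * dx * donor(v[k, j, i], cm, cp) * dts
                if j > 0:
                    dC[k, j - 1, i] -= flux / (grid.Hz[k, j - 1, i] * area)
                if j < ny:
                    dC[k, j, i] += flux / (grid.Hz[k, j, i] * area)
    for k in range(nz + 1):
        for j in range(ny):
            for i in range(nx):
                cm = C[max(k - 1, 0), j, i]
                cp = C[min(k, nz - 1), j, i]
                flux = w[k, j, i] * area * donor(w[k, j, i], cm, cp) * dts
                if k > 0:
                    dC[k - 1, j, i] -= flux / (grid.Hz[k - 1, j, i] * area)
                if k < nz:
                    dC[k, j, i] += flux / (grid.Hz[k, j, i] * area)
                if k == 0:
                    dep[j, i] = -flux
    return C + dC, dep


class TestDiagnoseW:
    def test_zero_flow_zero_w(self, small_grid):
        w = diagnose_w(small_grid, _snapshot(small_grid))
        assert np.all(w.w == 0.0)
        assert w.surface_residual == 0.0

    def test_uniform_flow_flat_bottom_zero_w(self):
        b = Bathymetry(depth=np.full((4, 6), 800.0), dx=250.0, dy=250.0)
        grid = build_grid(b, 5)
        nz, ny, nx = grid.shape
        snap = _snapshot(grid, u=np.full((nz, ny, nx + 1), 0.3),
                         v=np.full((nz, ny + 1, nx), -0.2))
        w = diagnose_w(grid, snap)
        assert np.abs(w.w).max() < 1e-14

    def test_depth_step_matches_column_sum_oracle(self):
        """1-D flow over a depth step: w equals the brute-force cumulative
        sum of per-layer face-flux divergences."""
        depth = np.array([[1000.0, 1000.0, 500.0, 500.0]])
        b = Bathymetry(depth=depth, dx=250.0, dy=250.0)
        grid = build_grid(b, 6)
        nz, ny, nx = grid.shape
        hz_u = grid.hz_u()
        H_u = hz_u.sum(axis=0)
        u = np.broadcast_to((0.2 * 1000.0 / H_u)[None], (nz, ny, nx + 1)).copy()
        snap = _snapshot(grid, u=u)
        w = diagnose_w(grid, snap)
        Fu, Fv = _face_fluxes(grid, snap)
        for (j, i) in [(0, 1), (0, 2)]:
            acc = 0.0
            for k in range(nz):
                acc -= (Fu[k, j, i + 1] - Fu[k, j, i]) + (
                    Fv[k, j + 1, i] - Fv[k, j, i]
                )
                assert w.w[k + 1, j, i] == pytest.approx(
                    acc / grid.cell_area, abs=1e-15
                )

    def test_shape_mismatch_rejected(self, small_grid):
        nz, ny, nx = small_grid.shape
        bad = FlowSnapshot(u=np.zeros((nz, ny, nx)), v=np.zeros((nz, ny + 1, nx)),
                           time=0.0)
        with pytest.raises(ValueError, match="match"):
            diagnose_w(small_grid, bad)


class TestInterpFlow:
    def _series(self, grid):
        nz, ny, nx = grid.shape
        snaps = []
        for t, val in [(0.0, 0.0), (0.25, 0.2), (0.5, -0.1)]:
            snaps.append(_snapshot(grid, u=np.full((nz, ny, nx + 1), val), t=t))
        return FlowSeries(snaps)

    def test_snapshot_time_identity(self, small_grid):
        series = self._series(small_grid)
        snap = interp_flow(series, 0.25)
        assert np.array_equal(snap.u, series[1].u)

    def test_linear_midpoint(self, small_grid):
        series = self._series(small_grid)
        snap = interp_flow(series, 0.125)
        assert np.allclose(snap.u, 0.1)

    def test_affine_within_interval(self, small_grid):
        series = self._series(small_grid)
        t = np.array([0.30, 0.35, 0.40])
        vals = [interp_flow(series, ti).u[0, 0, 0] for ti in t]
        slope1 = (vals[1] - vals[0]) / 0.05
        slope2 = (vals[2] - vals[1]) / 0.05
        assert slope1 == pytest.approx(slope2, rel=1e-9)

    def test_out_of_span_rejected(self, small_grid):
        with pytest.raises(ValueError, match="span"):
            interp_flow(self._series(small_grid), 1.0)


class TestAdvectUpwind:
    def test_zero_velocity_is_identity(self, small_grid):
        nz, ny, nx = small_grid.shape
        rng = np.random.default_rng(0)
        state = TracerState(rng.uniform(0, 1, (nz, ny, nx)), 0.0)
        w = np.zeros((nz + 1, ny, nx))
        new, fluxes = advect_upwind(state, small_grid, _snapshot(small_grid), w, 0.01)
        assert np.array_equal(new.concentration, state.concentration)
        assert np.all(fluxes.deposition == 0.0)

    def test_uniform_tracer_preserved_by_divergence_free_flow(self, study_domain):
        grid, _ = study_domain
        flows = make_tidal_flow(grid, TidalForcing(), 0.1, 0.4, 6.0)
        snap = flows[0]
        w = diagnose_w(grid, snap).w
        state = TracerState(np.full(grid.shape, 0.37), 0.0)
        dt = cfl_max_dt(grid, snap, w)
        new, _ = advect_upwind(state, grid, snap, w, dt)
        assert np.max(np.abs(new.concentration - 0.37)) < 1e-12

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_loop_oracle_on_small_instances(self, seed):
        """Vectorised kernel equals the independent loop-based donor-cell
        update on random <= 5x5x5 instances."""
        rng = np.random.default_rng(seed)
        grid = _random_grid(rng, nz=rng.integers(2, 6), ny=rng.integers(2, 6),
                            nx=rng.integers(2, 6))
        nz, ny, nx = grid.shape
        u = rng.uniform(-0.5, 0.5, (nz, ny, nx + 1))
        v = rng.uniform(-0.5, 0.5, (nz, ny + 1, nx))
        w = rng.uniform(-2e-3, 2e-3, (nz + 1, ny, nx))
        w[0] = -rng.uniform(0, 200.0, (ny, nx)) / SECONDS_PER_DAY
        C = rng.uniform(0, 2.0, (nz, ny, nx))
        snap = _snapshot(grid, u=u, v=v)
        dt = 0.5 * cfl_max_dt(grid, snap, w)
        new, fluxes = advect_upwind(TracerState(C, 0.0), grid, snap, w, dt)
        expected, dep = donor_cell_oracle(grid, C, u, v, w, dt)
        assert np.max(np.abs(new.concentration - expected)) < 1e-12
        assert np.max(np.abs(fluxes.deposition - dep)) < 1e-9 * max(dep.max(), 1)

    def test_mass_conserved_with_closed_boundaries(self):
        rng = np.random.default_rng(7)
        grid = _random_grid(rng, nz=4, ny=4, nx=5)
        nz, ny, nx = grid.shape
        u = rng.uniform(-0.3, 0.3, (nz, ny, nx + 1))
        v = rng.uniform(-0.3, 0.3, (nz, ny + 1, nx))
        w = rng.uniform(-1e-3, 1e-3, (nz + 1, ny, nx))
        u[:, :, 0] = u[:, :, -1] = 0.0
        v[:, 0, :] = v[:, -1, :] = 0.0
        w[0] = w[-1] = 0.0
        C = rng.uniform(0, 1.0, (nz, ny, nx))
        snap = _snapshot(grid, u=u, v=v)
        dt = cfl_max_dt(grid, snap, w)
        vol = grid.cell_volume
        mass0 = (C * vol).sum()
        state = TracerState(C, 0.0)
        for _ in range(5):
            state, fluxes = advect_upwind(state, grid, snap, w, dt)
            assert fluxes.lateral_export == 0.0
        mass1 = (state.concentration * vol).sum()
        assert abs(mass1 - mass0) / mass0 < 1e-10

    def test_no_new_extrema_under_cfl(self, study_domain):
        """Donor-cell advection with a continuity-closed velocity field never
        creates concentrations outside the initial range."""
        grid, _ = study_domain
        flows = make_tidal_flow(grid, TidalForcing(), 0.3, 0.6, 6.0)
        snap = flows[0]
        w = diagnose_w(grid, snap).w
        rng = np.random.default_rng(11)
        C = rng.uniform(0.2, 1.7, grid.shape)
        state = TracerState(C, 0.0)
        lo, hi = C.min(), C.max()
        dt = cfl_max_dt(grid, snap, w)
        for _ in range(5):
            state, _ = advect_upwind(state, grid, snap, w, dt)
            assert state.concentration.min() >= lo - 1e-12
            assert state.concentration.max() <= hi + 1e-12

    def test_cfl_violation_raises(self, small_grid):
        nz, ny, nx = small_grid.shape
        u = np.full((nz, ny, nx + 1), 1.0)
        snap = _snapshot(small_grid, u=u)
        w = np.zeros((nz + 1, ny, nx))
        state = TracerState(np.ones((nz, ny, nx)), 0.0)
        with pytest.raises(ValueError, match="CFL"):
            advect_upwind(state, small_grid, snap, w, dt=1.0)


class TestCflMaxDt:
    def test_zero_flow_returns_cap(self, small_grid):
        nz, ny, nx = small_grid.shape
        w = np.zeros((nz + 1, ny, nx))
        assert cfl_max_dt(small_grid, _snapshot(small_grid), w, cap=0.05) == 0.05

    def test_single_face_courant_definition(self):
        """One active face with |u| = dx per day gives dt = safety * 1 d."""
        b = Bathymetry(depth=np.full((1, 2), 100.0), dx=250.0, dy=250.0)
        grid = build_grid(b, 2, theta_s=0.0, theta_b=0.0)
        u = np.zeros((2, 1, 3))
        u[0, 0, 1] = 250.0 / SECONDS_PER_DAY
        snap = _snapshot(grid, u=u)
        w = np.zeros((3, 1, 2))
        dt = cfl_max_dt(grid, snap, w, cap=10.0)
        assert dt == pytest.approx(0.8, rel=1e-12)

    def test_matches_exhaustive_cell_scan(self):
        rng = np.random.default_rng(3)
        grid = _random_grid(rng, nz=3, ny=4, nx=5)
        nz, ny, nx = grid.shape
        u = rng.uniform(-0.5, 0.5, (nz, ny, nx + 1))
        v = rng.uniform(-0.5, 0.5, (nz, ny + 1, nx))
        w = rng.uniform(-2e-3, 2e-3, (nz + 1, ny, nx))
        snap = _snapshot(grid, u=u, v=v)
        hz_u, hz_v = grid.hz_u(), grid.hz_v()
        worst = 0.0
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    out = (
                        max(u[k, j, i + 1], 0) * hz_u[k, j, i + 1] * grid.dy
                        + max(-u[k, j, i], 0) * hz_u[k, j, i] * grid.dy
                        + max(v[k, j + 1, i], 0) * hz_v[k, j + 1, i] * grid.dx
                        + max(-v[k, j, i], 0) * hz_v[k, j, i] * grid.dx
                        + max(w[k + 1, j, i], 0) * grid.cell_area
                        + max(-w[k, j, i], 0) * grid.cell_area
                    )
                    worst = max(worst, out / (grid.Hz[k, j, i] * grid.cell_area))
        expected = min(10.0, 0.8 / (worst * SECONDS_PER_DAY))
        assert cfl_max_dt(grid, snap, w, cap=10.0) == pytest.approx(expected, rel=1e-12)
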