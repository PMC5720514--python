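"""Tissue solver: tensors, grids, diffusion properties, walls, CV scaling."""

import numpy as np
import pytest

import eadsim._kernels as K
from eadsim import build_params
from eadsim.metrics import activation_time, measure_cv
from eadsim.tissue import (StimEvent, build_grid, build_links,
                           conductivity_from_fibers, insert_walls,
                           local_tensor, run_simulation)


class TestLocalTensor:
    def test_axis_aligned_fiber_gives_diagonal(self):
        D = local_tensor((1.0, 0.0, 0.0), dl=0.00154, dt_ratio=4.0)
        assert np.allclose(np.diag(D), [0.00154, 0.000385, 0.000385])
        assert np.allclose(D, np.diag(np.diag(D)))

    def test_unit_ratio_is_isotropic(self):
        f = np.array([1.0, 2.0, -1.0])
        f /= np.linalg.norm(f)
        D = local_tensor(f, dl=0.002, dt_ratio=1.0)
        assert np.allclose(D, 0.002 * np.eye(3))

    def test_rotation_conjugates_tensor(self):
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        f0 = np.array([1.0, 0.0, 0.0])
        D0 = local_tensor(f0)
        D1 = local_tensor(R @ f0)
        assert np.allclose(D1, R @ D0 @ R.T)
        assert np.allclose(np.sort(np.linalg.eigvalsh(D1)),
                           np.sort(np.linalg.eigvalsh(D0)))

    def test_non_unit_fiber_rejected(self):
        with pytest.raises(ValueError):
            local_tensor((1.0, 1.0, 0.0))


class TestBuildGrid:
    def test_cable_8cm(self):
        g = build_grid("cable", 8.0, 0.04)
        assert g.shape == (200,)
        assert np.allclose(g.fibers[..., 0], 1.0)

    def test_sheet_4cm(self):
        g = build_grid("sheet", (4.0, 4.0), 0.04)
        assert g.shape == (100, 100)

    def test_wedge_fiber_rotation(self):
        g = build_grid("wedge", (1.0, 0.6, 0.6), 0.1)
        nz = g.shape[2]
        ang = np.degrees(np.arctan2(g.fibers[0, 0, :, 1],
                                    g.fibers[0, 0, :, 0]))
        assert ang[0] == pytest.approx(-60.0)
        assert ang[-1] == pytest.approx(60.0)
        assert ang[nz // 2] == pytest.approx(0.0, abs=60.0 / (nz - 1))
        assert np.allclose(np.linalg.norm(g.fibers, axis=-1), 1.0)

    def test_wedge_paper_dimensions(self):
        g = build_grid("wedge", (8.0, 4.0, 4.0), 0.04)
        assert g.shape == (200, 100, 100)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            build_grid("cable", 0.05, 0.04)


def _diffuse_only(grid, cond, v0, n_steps, dt=0.02):
    """Pure diffusion via the solver's link kernel (reaction off)."""
    inside_idx, la, lb, lw, cross = build_links(grid, cond)
    v = v0.ravel()[inside_idx].astype(float).copy()
    out = np.zeros_like(v)
    for _ in range(n_steps):
        K._diffusion(v, la, lb, lw, out)
        if cross[0]:
            for p in range(cross[1].shape[0]):
                K._cross_terms(v, cross[1][p], cross[2][p], cross[3][p],
                               out, cross[4])
        v += dt * out
    full = v0.astype(float).ravel().copy()
    full[inside_idx] = v
    return full.reshape(grid.shape)


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        g = build_grid("sheet", (1.0, 1.0), 0.04)
        cond = conductivity_from_fibers(g)
        v0 = np.full(g.shape, -30.0)
        v1 = _diffuse_only(g, cond, v0, 100)
        assert np.allclose(v1, v0)

    def test_conservation_and_maximum_principle(self):
        g = build_grid("sheet", (1.0, 1.0), 0.04)
        cond = conductivity_from_fibers(g)
        rng = np.random.default_rng(7)
        v0 = rng.uniform(-80.0, 20.0, g.shape)
        v1 = _diffuse_only(g, cond, v0, 200)
        assert np.mean(v1) == pytest.approx(np.mean(v0), abs=1e-10)
        assert v1.max() <= v0.max() + 1e-12
        assert v1.min() >= v0.min() - 1e-12

    def test_off_axis_fibers_conserve_too(self):
        g = build_grid("sheet", (1.0, 1.0), 0.04, fiber_spec=30.0)
        cond = conductivity_from_fibers(g)
        rng = np.random.default_rng(3)
        v0 = rng.uniform(-80.0, 20.0, g.shape)
        v1 = _diffuse_only(g, cond, v0, 50)
        assert np.mean(v1) == pytest.approx(np.mean(v0), abs=1e-6)

    def test_rotated_fibers_spread_along_fiber_axis(self):
        # pure diffusion of a Gaussian on a 45-degree fiber field must
        # spread preferentially along the fiber diagonal
        g = build_grid("sheet", (2.0, 2.0), 0.04, fiber_spec=45.0)
        cond = conductivity_from_fibers(g)
        n = g.shape[0]
        x, y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        v0 = np.exp(-((x - n / 2) ** 2 + (y - n / 2) ** 2) / 18.0)
        v1 = _diffuse_only(g, cond, v0, 2000)
        c = n // 2
        diag = np.array([v1[c + k, c + k] for k in range(-15, 16)])
        anti = np.array([v1[c + k, c - k] for k in range(-15, 16)])
        w_diag = (diag / diag.max() > 0.5).sum()
        w_anti = (anti / anti.max() > 0.5).sum()
        assert w_diag > 1.4 * w_anti

    def test_anisotropic_wavefront_axis_ratio(self, default_params):
        # CV scales as sqrt(D): a 4:1 tensor gives a 2:1 elliptical front
        g = build_grid("sheet", (2.0, 2.0), 0.04)
        cond = conductivity_from_fibers(g, dl=0.00154, dt_ratio=4.0)
        c = g.shape[0] // 2
        center = [c * g.shape[1] + c + dj for dj in (-1, 0, 1)]
        center += [c2 * g.shape[1] + c for c2 in (c - 1, c + 1)]
        ev = StimEvent(nodes=np.array(center), start=1.0, duration=2.0)
        res = run_simulation(g, default_params, 25.0, cond=cond,
                             events=(ev,), sample_dt=1.0)
        act = np.asarray(res.movie.data[-1], float) > -20.0
        half_x = np.abs(np.nonzero(act[:, c])[0] - c).max()
        half_y = np.abs(np.nonzero(act[c, :])[0] - c).max()
        assert half_x / half_y == pytest.approx(2.0, rel=0.10)


class TestWalls:
    def test_no_planes_is_identity(self):
        g = build_grid("cable", 2.0, 0.04)
        assert insert_walls(g, []) == g

    def test_plane_outside_grid_rejected(self):
        g = build_grid("cable", 2.0, 0.04)
        with pytest.raises(ValueError):
            insert_walls(g, [(0, 5.0)])

    def test_wall_blocks_wave(self, default_params):
        g = build_grid("cable", 4.0, 0.04)
        gw = insert_walls(g, [(0, 2.02)])
        ev = StimEvent(nodes=np.arange(2), start=1.0, duration=1.0)
        res = run_simulation(gw, default_params, 500.0, events=(ev,))
        right = np.asarray(res.movie.data[:, 60:], float)
        assert right.max() < -60.0  # far side never activates

    def test_two_planes_make_four_independent_quadrants(self, default_params):
        g = build_grid("sheet", (1.6, 1.6), 0.04)
        n = g.shape[0]
        gw = insert_walls(g, [(0, 0.81), (1, 0.81)])
        # stimulate only the lower-left quadrant
        nodes = np.array([i * n + j for i in range(3) for j in range(3)])
        res = run_simulation(gw, default_params, 200.0,
                             events=(StimEvent(nodes=nodes, start=1.0,
                                               duration=2.0),))
        vmax = np.asarray(res.movie.data, float).max(axis=0)
        assert vmax[:20, :20].max() > 0.0          # stimulated quadrant fires
        assert vmax[21:, :].max() < -60.0           # others stay quiescent
        assert vmax[:, 21:].max() < -60.0


class TestConductionVelocity:
    def test_cv_scales_as_sqrt_d(self, sqrt_d_cvs):
        # physics check on a resolved front (see the sqrt_d_cvs fixture)
        assert sqrt_d_cvs[1.0] / sqrt_d_cvs[0.25] == \
            pytest.approx(2.0, rel=0.05)
        assert sqrt_d_cvs[4.0] / sqrt_d_cvs[1.0] == \
            pytest.approx(2.0, rel=0.05)

    def test_unstable_timestep_is_flagged(self, default_params):
        grid = build_grid("cable", 1.0, 0.005)
        cond = conductivity_from_fibers(grid, dl=4 * 0.00154)
        with pytest.warns(UserWarning, match="stability"):
            try:
                run_simulation(grid, default_params, 20.0, cond=cond,
                               dt=0.02,
                               events=(StimEvent(nodes=np.arange(4),
                                                 start=1.0, duration=1.0),))
            except Exception:
                pass  # blow-up after the warning is expected


def test_step_tissue_single_step_matches_run(default_params):
    from eadsim.tissue import step_tissue, uniform_states
    g = build_grid("cable", 1.0, 0.04)
    cond = conductivity_from_fibers(g)
    states = uniform_states(g)
    v0 = np.full(g.shape, -86.2)
    v1 = step_tissue(v0, states, g, cond, default_params, dt=0.02)
    assert v1.shape == g.shape
    assert np.all(np.abs(v1 - v0) < 0.01)  # rest barely moves in one step
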