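"""Unit checks of every force term, including finite-difference energy
oracles for the conservative terms."""

import numpy as np
import pytest

from epiwave.geometry import BoundaryPolygon, outward_normal, polygon_measures
from epiwave.model import (
    ModelParams,
    PhaseProgram,
    Simulation,
    apply_oocyte_growth,
    force_adhesion,
    force_area,
    force_fiber,
    force_noise,
    force_rac,
    force_tension,
    hill_factor,
)
from epiwave.geometry import hexagonal_tiling


def star_polygon(rng, n=20, r_lo=1.0, r_hi=2.0):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = rng.uniform(r_lo, r_hi, n)
    return BoundaryPolygon(np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1))


class TestForceTension:
    def test_midpoint_equilibrium(self):
        f = force_tension((0, 0), (1, 0), (-1, 0), 1.0)
        assert f == pytest.approx([0.0, 0.0], abs=1e-15)

    def test_vector_sum(self):
        f = force_tension((0, 0), (1, 0), (0, 1), 1.0)
        assert f == pytest.approx([1.0, 1.0], abs=1e-15)

    def test_energy_gradient_oracle(self):
        # E = (K_L/2) * sum over edges |edge|^2; F must equal -dE/dx
        rng = np.random.default_rng(0)
        k_l = 0.7
        for _ in range(20):
            poly = star_polygon(rng)
            v = poly.vertices.copy()
            n = v.shape[0]
            i = int(rng.integers(0, n))

            def energy(pos):
                seg = np.roll(pos, -1, axis=0) - pos
                return 0.5 * k_l * np.sum(seg**2)

            h = 1e-6
            grad = np.zeros(2)
            for d in (0, 1):
                vp, vm = v.copy(), v.copy()
                vp[i, d] += h
                vm[i, d] -= h
                grad[d] = (energy(vp) - energy(vm)) / (2 * h)
            f = force_tension(v[i], v[(i - 1) % n], v[(i + 1) % n], k_l)
            assert np.linalg.norm(f + grad) < 1e-4 * max(np.linalg.norm(grad), 1e-9)


class TestForceArea:
    def test_zero_at_target_area(self):
        sq = BoundaryPolygon(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        f = force_area(sq, 0, k_a=2.0, a0=1.0)
        assert f == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_restoring_when_inflated(self):
        sq = BoundaryPolygon(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        f = force_area(sq, 2, k_a=1.0, a0=0.5)
        r_nor = outward_normal(sq, 2)
        assert float(f @ r_nor) < 0

    def test_inflated_square_magnitude(self):
        # unit square scaled so A = 1.1 * A0; |F| = K_a * s_hat * 0.1 * A0
        a0, k_a = 1.0, 3.0
        s = np.sqrt(1.1)
        sq = BoundaryPolygon(s * np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        for i in range(4):
            f = force_area(sq, i, k_a=k_a, a0=a0, variant="cortical")
            s_hat = s  # both adjacent edges have length s
            assert np.linalg.norm(f) == pytest.approx(k_a * s_hat * 0.1 * a0, abs=1e-9)

    def test_energy_gradient_oracle(self):
        # gradient variant: F = -d/dx of (K_a/2)(A - A0)^2
        rng = np.random.default_rng(1)
        k_a, a0 = 0.8, 2.0
        for _ in range(20):
            poly = star_polygon(rng)
            v = poly.vertices.copy()
            n = v.shape[0]
            i = int(rng.integers(0, n))

            def energy(pos):
                x, y = pos[:, 0], pos[:, 1]
                area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
                return 0.5 * k_a * (area - a0) ** 2

            h = 1e-6
            grad = np.zeros(2)
            for d in (0, 1):
                vp, vm = v.copy(), v.copy()
                vp[i, d] += h
                vm[i, d] -= h
                grad[d] = (energy(vp) - energy(vm)) / (2 * h)
            f = force_area(poly, i, k_a=k_a, a0=a0, variant="gradient")
            assert np.linalg.norm(f + grad) < 1e-4 * max(np.linalg.norm(grad), 1e-9)


class TestForceRac:
    def test_peak_at_mid_pulse(self):
        f_rac, sigma, duration = 2.0, 4.0, 20.0
        f = force_rac(duration / 2, 0.0, f_rac, sigma, duration, (1, 0))
        assert np.linalg.norm(f) == pytest.approx(
            f_rac / (sigma * np.sqrt(2 * np.pi)), abs=1e-12
        )

    def test_inactive_is_zero(self):
        f = force_rac(5.0, 0.0, 2.0, 4.0, 20.0, (1, 0), active=False)
        assert f == pytest.approx([0.0, 0.0])

    def test_gaussian_shape_symmetric(self):
        f_rac, sigma, duration = 2.0, 4.0, 20.0
        peak = f_rac / (sigma * np.sqrt(2 * np.pi))
        lo = force_rac(duration / 2 - sigma, 0.0, f_rac, sigma, duration, (1, 0))
        hi = force_rac(duration / 2 + sigma, 0.0, f_rac, sigma, duration, (1, 0))
        assert np.linalg.norm(lo) == pytest.approx(peak * np.exp(-0.5), rel=1e-12)
        assert np.linalg.norm(lo) == pytest.approx(np.linalg.norm(hi), rel=1e-12)

    def test_outside_window_is_zero(self):
        assert force_rac(25.0, 0.0, 2.0, 4.0, 20.0, (1, 0)) == pytest.approx([0, 0])


class TestForceAdhesion:
    def test_zero_rho_gives_zero(self):
        f = force_adhesion((0, 0), (1, 1), 1.0, 0.0, 1.0, 2.0)
        assert f == pytest.approx([0.0, 0.0])

    def test_half_saturation(self):
        # L_Rho^n = K_d -> F = (f_CAMs/2)(anchor - vertex)
        f = force_adhesion((0, 0), (2, 0), f_cams=3.0, l_rho=1.0, k_d=1.0, n=2.0)
        assert f == pytest.approx([3.0, 0.0], abs=1e-12)

    def test_hill_monotone(self):
        grid = np.linspace(0, 5, 200)
        vals = [hill_factor(l, 1.3, 2.0) for l in grid]
        assert np.all(np.diff(vals) >= 0)

    def test_negative_rho_raises(self):
        with pytest.raises(ValueError):
            force_adhesion((0, 0), (1, 0), 1.0, -0.1, 1.0, 2.0)


class TestForceFiber:
    def test_zero_at_rest_length(self):
        fa, fb = force_fiber((0, 0), (0, 2), 2.0, 2.0)
        assert fa == pytest.approx([0, 0]) and fb == pytest.approx([0, 0])

    def test_no_compression_support(self):
        fa, fb = force_fiber((0, 0), (0, 1), 2.0, 2.0)
        assert fa == pytest.approx([0, 0]) and fb == pytest.approx([0, 0])

    def test_linear_spring_pair(self):
        fa, fb = force_fiber((0, 0), (0, 3), k_fiber=2.0, rest_len=2.0)
        assert np.linalg.norm(fa) == pytest.approx(2.0)
        assert fa + fb == pytest.approx([0.0, 0.0], abs=1e-15)
        assert fa[1] > 0  # pulls endpoints together

    def test_coincident_endpoints_raise(self):
        with pytest.raises(ValueError):
            force_fiber((1, 1), (1, 1), 1.0, 1.0)


class TestForceNoise:
    def test_zero_strength(self, rng):
        assert force_noise(0.0, rng) == pytest.approx([0.0, 0.0])

    def test_moments(self, rng):
        f_r = 0.7
        draws = np.array([force_noise(f_r, rng) for _ in range(100_000)])
        assert np.abs(draws.mean(axis=0)).max() < 3 * f_r / np.sqrt(100_000)
        assert draws.var(axis=0) == pytest.approx(f_r**2, rel=0.05)


class TestOocyteGrowth:
    def test_zero_rate_unchanged(self):
        anchors = np.array([[0.0, 1.0], [5.0, -1.0]])
        out = apply_oocyte_growth(anchors, 0.0, 0.1, x_posterior=10.0)
        np.testing.assert_array_equal(out, anchors)

    def test_affine_stretch(self):
        anchors = np.array([[0.0, 2.0]])  # 10 um from posterior edge
        out = apply_oocyte_growth(anchors, g=1.0, dt=0.01, x_posterior=10.0)
        assert out[0, 0] == pytest.approx(-0.1)  # moves 0.1 um anteriorly
        assert out[0, 1] == 2.0  # D-V untouched

    def test_dv_never_changes(self, rng):
        anchors = rng.uniform(-5, 5, (40, 2))
        out = apply_oocyte_growth(anchors, 0.01, 0.05, x_posterior=5.0)
        np.testing.assert_array_equal(out[:, 1], anchors[:, 1])


class TestStep:
    def test_fixed_point_when_all_forces_vanish(self):
        params = ModelParams(
            line_tension=1e-30,
            rac_strength=0.0,
            noise_strength=0.0,
            fiber_stiffness=1e-30,
        )
        program = PhaseProgram(growth_rate=0.0, tension_rho_coupling=False)
        mesh = hexagonal_tiling(2, 2, 2.0, 3)
        sim = Simulation(mesh, params, program, "WT", seed=0)
        before = sim.mesh.vertex_pool.copy()
        for _ in range(50):
            sim.step()
        np.testing.assert_allclose(sim.mesh.vertex_pool, before, atol=1e-12)

    def test_single_vertex_relaxes_to_midpoint(self):
        # one free vertex under pure tension: matches the closed-form
        # linear ODE x(t) = m + (x0 - m) exp(-2 K_L t / eta)
        k_l, eta, dt = 0.3, 1.0, 1e-3
        a, b = np.array([1.0, 0.0]), np.array([-1.0, 2.0])
        mid = 0.5 * (a + b)
        x = np.array([4.0, -3.0])
        dists = [np.linalg.norm(x - mid)]
        for _ in range(2000):
            f = force_tension(x, a, b, k_l)
            x = x + dt / eta * f
            dists.append(np.linalg.norm(x - mid))
        dists = np.array(dists)
        assert np.all(np.diff(dists) <= 1e-12)  # monotone decay
        t_final = 2000 * dt
        expected = dists[0] * np.exp(-2 * k_l * t_final / eta)
        assert dists[-1] == pytest.approx(expected, rel=1e-3)

    def test_nonfinite_position_aborts(self):
        params = ModelParams(noise_strength=0.0)
        mesh = hexagonal_tiling(1, 1, 2.0, 3)
        sim = Simulation(mesh, params, PhaseProgram(), "WT", seed=0)
        sim.mesh.vertex_pool[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            for _ in range(100):
                sim.step()

    def test_unstable_dt_rejected(self):
        params = ModelParams(dt=5.0)
        mesh = hexagonal_tiling(1, 1, 2.0, 3)
        with pytest.raises(ValueError, match="stability"):
            Simulation(mesh, params, PhaseProgram(), "WT", seed=0)


class TestEngineMatchesUnitForces:
    """The vectorised assembly must agree with the scalar force functions."""

    def test_tension_and_area_assembly(self):
        params = ModelParams(
            noise_strength=0.0, rac_strength=0.0, cam_strength=0.0,
            fiber_stiffness=1e-30,
        )
        program = PhaseProgram(growth_rate=0.0, tension_rho_coupling=False)
        mesh = hexagonal_tiling(2, 2, 2.0, 3)
        rng = np.random.default_rng(9)
        mesh.vertex_pool += rng.normal(0, 0.1, mesh.vertex_pool.shape)
        sim = Simulation(mesh, params, program, "WT", seed=0)
        assembled = sim.compute_forces()
        expected = np.zeros_like(assembled)
        for ci in range(sim.n_cells):
            loop = sim.mesh.cells[ci]
            poly = sim.mesh.cell_polygon(ci)
            n = loop.size
            for k in range(n):
                vi = int(loop[k])
                v = sim.mesh.vertex_pool
                expected[vi] += force_tension(
                    v[vi], v[int(loop[(k - 1) % n])], v[int(loop[(k + 1) % n])],
                    params.line_tension,
                )
                expected[vi] += force_area(
                    poly, k, params.area_stiffness, sim.a0_init[ci], variant="gradient"
                )
        np.testing.assert_allclose(assembled, expected, atol=1e-10)
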