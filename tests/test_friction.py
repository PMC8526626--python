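"""Coulomb friction vector, weight normalisation, and friction maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from slithersim import (
    BodyGrid,
    Disk,
    EnvironmentParams,
    FrictionMap,
    GaitParams,
    RadialGradient,
    Raster,
    Strip,
    friction_coefficient_vector,
    friction_force_density,
    froude_number,
    lifting_modulation,
    local_scale,
    normalized_weight,
    reconstruct_configuration,
    regularized_direction,
)
from slithersim.dynamics import SnakeState

angles = st.floats(-np.pi, np.pi)


def frame(beta):
    t_hat = np.array([np.cos(beta), np.sin(beta)])
    n_hat = np.array([-np.sin(beta), np.cos(beta)])
    return t_hat, n_hat


class TestRegularizedDirection:
    def test_zero_velocity(self):
        assert regularized_direction(np.zeros(2), 1e-6) == pytest.approx(np.zeros(2))

    def test_fast_sliding_limit(self):
        v = np.array([3.0, -4.0]) * 1000 * 1e-6
        u = regularized_direction(v, 1e-6)
        assert u == pytest.approx(v / np.linalg.norm(v), abs=1e-6)

    def test_at_regularization_scale(self):
        u = regularized_direction(np.array([1e-6, 0.0]), 1e-6)
        assert u == pytest.approx(np.array([1 / np.sqrt(2), 0.0]))

    @given(vx=st.floats(-10, 10), vy=st.floats(-10, 10))
    def test_bounded_by_one(self, vx, vy):
        assert np.linalg.norm(regularized_direction(np.array([vx, vy]), 1e-3)) <= 1.0 + 1e-12

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            regularized_direction(np.zeros(2), 0.0)


class TestFrictionVector:
    def test_forward_sliding(self):
        t_hat, n_hat = frame(0.3)
        env = EnvironmentParams(mu_t_ratio=2.0, mu_b_ratio=1.5)
        assert friction_coefficient_vector(t_hat, t_hat, n_hat, env) == pytest.approx(t_hat)

    def test_transverse_sliding(self):
        t_hat, n_hat = frame(-0.8)
        env = EnvironmentParams(mu_t_ratio=2.0)
        assert friction_coefficient_vector(n_hat, t_hat, n_hat, env) == pytest.approx(2.0 * n_hat)

    def test_backward_sliding(self):
        t_hat, n_hat = frame(1.1)
        env = EnvironmentParams(mu_t_ratio=2.0, mu_b_ratio=1.5)
        assert friction_coefficient_vector(-t_hat, t_hat, n_hat, env) == pytest.approx(-1.5 * t_hat)

    @given(beta=angles, psi=angles)
    def test_decomposition(self, beta, psi):
        """mu.n = (mu_t/mu_f)(u.n); mu.t is (u.t) scaled by 1 or mu_b/mu_f by slip sign."""
        t_hat, n_hat = frame(beta)
        u = np.array([np.cos(psi), np.sin(psi)])
        env = EnvironmentParams(mu_t_ratio=3.0, mu_b_ratio=1.5)
        mu = friction_coefficient_vector(u, t_hat, n_hat, env)
        un, ut = u @ n_hat, u @ t_hat
        assert mu @ n_hat == pytest.approx(3.0 * un, abs=1e-12)
        expected_t = ut if ut > 0 else 1.5 * ut
        if abs(ut) > 1e-9:
            assert mu @ t_hat == pytest.approx(expected_t, abs=1e-12)

    @given(psi=angles)
    def test_isotropic_degeneracy(self, psi):
        """With all ratios 1 the friction vector is the slip direction itself."""
        t_hat, n_hat = frame(0.0)
        u = np.array([np.cos(psi), np.sin(psi)])
        env = EnvironmentParams(mu_t_ratio=1.0, mu_b_ratio=1.0)
        assert friction_coefficient_vector(u, t_hat, n_hat, env) == pytest.approx(u, abs=1e-12)

    @given(beta=angles, psi=angles, axis=angles)
    def test_mirror_symmetry(self, beta, psi, axis):
        """Reflecting u, t, n about any axis reflects mu about the same axis."""

        def reflect(v):
            c, s = np.cos(2 * axis), np.sin(2 * axis)
            return np.array([c * v[0] + s * v[1], s * v[0] - c * v[1]])

        t_hat, n_hat = frame(beta)
        u = 0.9 * np.array([np.cos(psi), np.sin(psi)])
        env = EnvironmentParams(mu_t_ratio=2.0, mu_b_ratio=1.5)
        mu = friction_coefficient_vector(u, t_hat, n_hat, env)
        # reflection flips handedness: the reflected frame's +90-degree normal is -reflect(n)
        mu_ref = friction_coefficient_vector(reflect(u), reflect(t_hat), -reflect(n_hat), env)
        assert mu_ref == pytest.approx(reflect(mu), abs=1e-9)

    def test_non_unit_frame_rejected(self):
        env = EnvironmentParams()
        with pytest.raises(ValueError):
            friction_coefficient_vector(np.array([1.0, 0]), np.array([2.0, 0]), np.array([0, 1.0]), env)


class TestNormalizedWeight:
    def test_uniform(self, grid):
        assert normalized_weight(np.ones(grid.n_s), grid) == pytest.approx(np.ones(grid.n_s))

    @given(A=st.floats(0, 2.5), phi=st.floats(0, 0.999), t=st.floats(0, 3))
    def test_weight_conservation(self, grid, A, phi, t):
        """The normalised weight integrates to 1 for any lifting wave."""
        gait = GaitParams(A=A, phi=phi, lam=1.0)
        n = normalized_weight(lifting_modulation(grid.s_values, t, gait), grid)
        assert float(grid.integrate(n)) == pytest.approx(1.0, abs=1e-12)

    def test_eta_against_dense_oracle(self, grid):
        """Normalisation constant of a clipped wave matches a 10^4-node quadrature."""
        f = lambda s: np.maximum(0.0, 2 * np.cos(2 * np.pi * s) + 1)
        n = normalized_weight(f(grid.s_values), grid)
        eta = n[0] / f(grid.s_values)[0]
        s_dense = np.linspace(0, 1, 10_001)
        eta_oracle = 1.0 / np.trapezoid(f(s_dense), s_dense)
        assert eta == pytest.approx(eta_oracle, rel=1e-3)

    def test_degenerate_wave_rejected(self, grid):
        with pytest.raises(ValueError):
            normalized_weight(np.zeros(grid.n_s), grid)
        with pytest.raises(ValueError):
            normalized_weight(-np.ones(grid.n_s), grid)


class TestFrictionMap:
    def test_background_is_one(self):
        fmap = FrictionMap((Disk(center=(5, 5), diameter=1.0, scale=50.0),))
        assert local_scale(np.array([0.0, 0.0]), fmap) == 1.0
        assert local_scale(np.array([5.0, 5.0]), fmap) == 50.0

    def test_none_map(self):
        assert local_scale(np.array([1.0, 2.0]), None) == 1.0

    def test_radial_gradient_linear_profile(self):
        lens = RadialGradient(center=(0, 0), diameter=4.0, scale=9.0)
        # halfway to the rim: linear interpolation between 9 and 1
        assert local_scale(np.array([1.0, 0.0]), FrictionMap((lens,))) == pytest.approx(5.0)

    def test_raster_nearest_cell(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        fmap = FrictionMap((Raster(origin=(0, 0), cell_size=1.0, values=vals),))
        assert local_scale(np.array([0.5, 0.5]), fmap) == 1.0
        assert local_scale(np.array([1.5, 0.5]), fmap) == 2.0
        assert local_scale(np.array([0.5, 1.5]), fmap) == 3.0
        assert local_scale(np.array([2.5, 0.5]), fmap) == 1.0  # outside extent

    def test_strip_membership(self):
        strip = Strip(anchor=(0, 0), angle=0.0, width=1.0, scale=0.0)
        fmap = FrictionMap((strip,))
        assert local_scale(np.array([3.0, 0.4]), fmap) == 0.0
        assert local_scale(np.array([3.0, 0.6]), fmap) == 1.0

    def test_overlap_last_listed_wins(self):
        fmap = FrictionMap(
            (
                Disk(center=(0, 0), diameter=2.0, scale=10.0),
                Disk(center=(0, 0), diameter=1.0, scale=3.0),
            )
        )
        assert local_scale(np.array([0.0, 0.0]), fmap) == 3.0
        assert local_scale(np.array([0.7, 0.0]), fmap) == 10.0

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            FrictionMap((Disk(center=(0, 0), diameter=1.0, scale=-1.0),))


class TestForceDensity:
    def _straight_config(self, grid, speed):
        state = SnakeState(com_vel=np.array([speed, 0.0]))
        return reconstruct_configuration(state, GaitParams(epsilon=0.0), grid, 0.0)

    def test_forward_sliding_force(self, grid):
        """Uniform forward sliding gives F = -t at every node."""
        cfg = self._straight_config(grid, 100.0)
        env = EnvironmentParams(mu_t_ratio=2.0)
        force = friction_force_density(cfg, np.ones(grid.n_s), env)
        assert force == pytest.approx(-cfg.tangents, abs=1e-8)

    def test_rest_gives_zero_force(self, grid):
        cfg = self._straight_config(grid, 0.0)
        force = friction_force_density(cfg, np.ones(grid.n_s), EnvironmentParams())
        assert np.abs(force).max() == 0.0

    def test_patch_scaling_is_local_and_linear(self, grid):
        cfg = self._straight_config(grid, 100.0)  # body spans x in [-0.5, 0.5]
        disk = lambda p: FrictionMap((Disk(center=(0.4, 0.0), diameter=0.1, scale=p),))
        env_p = lambda p: EnvironmentParams(friction_map=disk(p))
        f1 = friction_force_density(cfg, np.ones(grid.n_s), env_p(2.0))
        f2 = friction_force_density(cfg, np.ones(grid.n_s), env_p(4.0))
        inside = disk(2.0).scale_at(cfg.positions) != 1.0
        assert inside.any() and not inside.all()
        assert f2[inside] == pytest.approx(2.0 * f1[inside])
        assert f2[~inside] == pytest.approx(f1[~inside])

    def test_bounded_by_coefficients(self, grid, default_gait):
        state = SnakeState(com_vel=np.array([0.2, 0.1]), alpha_bar_t=0.5)
        cfg = reconstruct_configuration(state, default_gait, grid, 0.3)
        env = EnvironmentParams(mu_t_ratio=2.0, mu_b_ratio=1.5)
        weight = np.full(grid.n_s, 1.3)
        force = friction_force_density(cfg, weight, env)
        assert np.linalg.norm(force, axis=1).max() <= 1.3 * 2.0 * (1 + 1e-12)


def test_froude_number_bookkeeping():
    # printed 3D parameters: L=0.35 m, tau=2 s, g=9.81 m/s^2, mu_f=0.089
    fr = froude_number(0.35, 2.0, 9.81, 0.089)
    assert round(fr, 1) == 0.1
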