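"""Tests for the modulated dynamical-system trajectory generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from errpref.trajectory import (
    ControllerParams,
    DegenerateGeometryError,
    InvalidObstacleError,
    InvalidStartError,
    NominalDynamics,
    ObstacleModel,
    Trajectory,
    UndefinedMetricError,
    basis_matrix,
    default_workspace,
    deviation_onset,
    eigenvalue_matrix,
    expected_full_trajectory,
    gamma,
    integrate_trajectory,
    min_obstacle_distance,
    modulation_matrix,
    path_length,
    simulate_costs,
    surface_distance,
)


@pytest.fixture
def unit_sphere():
    return ObstacleModel(center=np.zeros(3), axis_scales=np.ones(3),
                         shape_exponents=np.ones(3, dtype=int))


class TestGamma:
    @pytest.mark.parametrize("x, s, expected", [
        ((1, 0, 0), 1.0, 1.0),     # boundary point
        ((2, 0, 0), 1.0, 4.0),     # (2/1)^2
        ((2, 0, 0), 2.0, 1.0),     # s doubles the virtual radius
    ])
    def test_unit_sphere_values(self, unit_sphere, x, s, expected):
        assert gamma(np.array(x, float), unit_sphere, s) == pytest.approx(expected)

    def test_zero_at_center_one_on_boundary(self, unit_sphere):
        assert gamma(np.zeros(3), unit_sphere) == 0.0
        assert gamma(np.array([0.0, 0.0, 1.0]), unit_sphere) == pytest.approx(1.0)

    def test_invalid_obstacle_rejected(self):
        with pytest.raises(InvalidObstacleError):
            ObstacleModel(center=np.zeros(3), axis_scales=np.array([1.0, -1.0, 1.0]),
                          shape_exponents=np.ones(3, dtype=int))
        with pytest.raises(InvalidObstacleError):
            ObstacleModel(center=np.zeros(3), axis_scales=np.ones(3),
                          shape_exponents=np.array([1.5, 1.0, 1.0]))


class TestBasisMatrix:
    @pytest.mark.parametrize("x, normal", [
        ((2.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
        ((0.0, 3.0, 0.0), (0.0, 1.0, 0.0)),
    ])
    def test_radial_normal(self, unit_sphere, x, normal):
        E = basis_matrix(np.array(x), unit_sphere)
        np.testing.assert_allclose(E[:, 0], normal, atol=1e-12)

    def test_orthonormal(self, unit_sphere):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=3) * 2
            if gamma(x, unit_sphere) < 1e-6:
                continue
            E = basis_matrix(x, unit_sphere)
            np.testing.assert_allclose(E.T @ E, np.eye(3), atol=1e-10)

    def test_center_degenerate(self, unit_sphere):
        with pytest.raises(DegenerateGeometryError):
            basis_matrix(np.zeros(3), unit_sphere)


class TestEigenvalues:
    def test_boundary(self):
        D = eigenvalue_matrix(1.0, 3.0, 3)
        assert D[0, 0] == pytest.approx(0.0)
        assert D[1, 1] == D[2, 2] == pytest.approx(2.0)

    def test_far_field_limit(self):
        D = eigenvalue_matrix(1e12, 1.0, 3)
        np.testing.assert_allclose(np.diag(D), 1.0, atol=1e-11)

    @pytest.mark.parametrize("rho", [1.0, 2.0, 5.0, 8.0])
    def test_gamma_two_to_rho(self, rho):
        D = eigenvalue_matrix(2.0 ** rho, rho, 3)
        assert D[0, 0] == pytest.approx(0.5)
        assert D[1, 1] == pytest.approx(1.5)

    def test_zero_gamma_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            eigenvalue_matrix(0.0, 2.0, 3)


class TestModulationMatrix:
    def test_far_field_identity(self, unit_sphere):
        params = ControllerParams(reactivity=1.0, safety=1.0)
        M = modulation_matrix(np.array([1e3, 0.0, 0.0]), params, unit_sphere)
        assert np.max(np.abs(M - np.eye(3))) < 1e-4

    def test_normal_velocity_blocked_on_boundary(self, unit_sphere):
        params = ControllerParams(reactivity=4.0, safety=1.0)
        x = np.array([1.0, 0.0, 0.0])
        M = modulation_matrix(x, params, unit_sphere)
        v = np.array([1.0, 0.0, 0.0])  # purely normal
        np.testing.assert_allclose(M @ v, 0.0, atol=1e-12)

    def test_algebraic_oracle(self, unit_sphere):
        """M v must equal decompose-scale-recompose in the E basis."""
        rng = np.random.default_rng(7)
        params = ControllerParams(reactivity=3.0, safety=1.2)
        for _ in range(25):
            x = rng.normal(size=3) * 3
            g = gamma(x, unit_sphere, params.safety)
            if g < 0.1:
                continue
            v = rng.normal(size=3)
            M = modulation_matrix(x, params, unit_sphere)
            E = basis_matrix(x, unit_sphere, params.safety)
            D = eigenvalue_matrix(g, params.reactivity, 3)
            coeffs = E.T @ v
            recomposed = E @ (np.diag(D) * coeffs)
            np.testing.assert_allclose(M @ v, recomposed, atol=1e-10)


class TestIntegration:
    def test_no_obstacle_straight_line(self):
        # obstacle ~300 scale-lengths away: modulated path matches the
        # obstacle-free straight line (low reactivity far field)
        obstacle = ObstacleModel(center=np.array([0.0, 100.0, 0.0]),
                                 axis_scales=np.ones(3),
                                 shape_exponents=np.ones(3, dtype=int))
        nominal = NominalDynamics(target=np.array([0.5, 0.0, 0.0]))
        params = ControllerParams(reactivity=1.0, safety=1.0)
        traj = integrate_trajectory(np.array([-0.5, 0.0, 0.0]), nominal, params, obstacle)
        assert traj.completed
        assert np.max(np.abs(traj.states[:, 1:])) < 1e-3

    def test_through_obstacle_completes_without_penetration(self):
        obstacle, nominal, start = default_workspace()
        params = ControllerParams(reactivity=4.0, safety=1.2)
        traj = integrate_trajectory(start, nominal, params, obstacle)
        assert traj.completed
        g = gamma(traj.states, obstacle, params.safety)
        assert g.min() >= 1 - 1e-3
        assert np.linalg.norm(traj.states[-1] - nominal.target) < 1e-3

    def test_deterministic(self):
        obstacle, nominal, start = default_workspace()
        params = ControllerParams(reactivity=5.0, safety=1.3)
        t1 = integrate_trajectory(start, nominal, params, obstacle)
        t2 = integrate_trajectory(start, nominal, params, obstacle)
        assert np.array_equal(t1.states, t2.states)

    def test_start_inside_rejected(self, unit_sphere):
        nominal = NominalDynamics(target=np.array([2.0, 0.0, 0.0]))
        params = ControllerParams(reactivity=2.0, safety=1.0)
        with pytest.raises(InvalidStartError):
            integrate_trajectory(np.array([0.5, 0.0, 0.0]), nominal, params, unit_sphere)

    def test_times_uniform(self):
        obstacle, nominal, start = default_workspace()
        params = ControllerParams(reactivity=2.0, safety=1.1)
        traj = integrate_trajectory(start, nominal, params, obstacle)
        np.testing.assert_allclose(np.diff(traj.times), params.dt, atol=1e-12)


class TestPathLength:
    def test_two_states(self):
        traj = Trajectory(states=np.array([[0.0, 0, 0], [3.0, 4.0, 0]]),
                          times=np.array([0.0, 1.0]), completed=True)
        assert path_length(traj) == pytest.approx(5.0)

    def test_straight_line_collinear(self):
        t = np.linspace(0, 1, 57)
        states = np.outer(t, [1.0, 2.0, -1.0])
        traj = Trajectory(states=states, times=t, completed=True)
        assert path_length(traj) == pytest.approx(np.sqrt(6.0), abs=1e-12)

    def test_unit_circle(self):
        theta = np.linspace(0, 2 * np.pi, 10_001)
        states = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        traj = Trajectory(states=states, times=theta, completed=True)
        assert path_length(traj) == pytest.approx(2 * np.pi, abs=1e-4)

    def test_single_state_rejected(self):
        traj = Trajectory(states=np.zeros((1, 3)), times=np.zeros(1), completed=False)
        with pytest.raises(UndefinedMetricError):
            path_length(traj)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_oracle_equivalence(self, seed):
        """Path length equals a naive per-step loop on random paths."""
        rng = np.random.default_rng(seed)
        states = rng.normal(size=(40, 3))
        traj = Trajectory(states=states, times=np.arange(40.0), completed=True)
        expected = sum(float(np.linalg.norm(states[i + 1] - states[i]))
                       for i in range(39))
        assert path_length(traj) == pytest.approx(expected, abs=1e-10)


class TestMinObstacleDistance:
    def test_tangent_path(self, unit_sphere):
        xs = np.linspace(-3, 3, 501)
        states = np.column_stack([xs, np.full_like(xs, 1.5), np.zeros_like(xs)])
        traj = Trajectory(states=states, times=xs, completed=True)
        assert min_obstacle_distance(traj, unit_sphere) == pytest.approx(0.5, abs=1e-9)

    def test_touching_surface(self, unit_sphere):
        states = np.array([[2.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        traj = Trajectory(states=states, times=np.arange(3.0), completed=True)
        assert min_obstacle_distance(traj, unit_sphere) == pytest.approx(0.0, abs=1e-12)

    def test_center_reference_dialect(self, unit_sphere):
        states = np.array([[2.0, 0, 0], [3.0, 0, 0]])
        traj = Trajectory(states=states, times=np.arange(2.0), completed=True)
        assert min_obstacle_distance(traj, unit_sphere, reference="center") == pytest.approx(2.0)

    def test_brute_force_oracle(self):
        """Surface clearance equals per-sample radial root-finding by bisection."""
        obstacle = ObstacleModel(center=np.array([0.1, -0.2, 0.3]),
                                 axis_scales=np.array([0.5, 0.8, 1.1]),
                                 shape_exponents=np.array([1, 2, 1]))
        rng = np.random.default_rng(11)
        from scipy.optimize import brentq
        for _ in range(5):
            states = rng.normal(size=(30, 3)) * 3 + obstacle.center
            states = states[gamma(states, obstacle) > 1.1]
            traj = Trajectory(states=states, times=np.arange(len(states), dtype=float),
                              completed=True)
            dists = []
            for x in states:
                u = x - obstacle.center
                f = lambda k: gamma(obstacle.center + k * u, obstacle) - 1.0
                k = brentq(f, 0.0, 1.0, xtol=1e-14)
                dists.append(np.linalg.norm(u) * (1 - k))
            assert min_obstacle_distance(traj, obstacle) == pytest.approx(min(dists), abs=1e-8)


class TestExpectedFullTrajectory:
    def test_interruption_invariant(self):
        """Costs depend only on (rho, s), never on behavioral interruption."""
        obstacle, nominal, start = default_workspace()
        params = ControllerParams(reactivity=3.0, safety=1.2)
        c1 = expected_full_trajectory(params, nominal, obstacle, start)
        c2 = expected_full_trajectory(params, nominal, obstacle, start)
        assert c1 == c2

    def test_comfort_monotone_in_s(self):
        obstacle, nominal, start = default_workspace()
        svals = np.round(np.arange(1.0, 1.51, 0.1), 3)
        _, comfort, _, _ = simulate_costs(np.full(len(svals), 4.0), svals,
                                          nominal, obstacle, start)
        assert np.all(np.diff(comfort) >= -1e-9)

    def test_higher_reactivity_deviates_earlier(self):
        obstacle, nominal, start = default_workspace()
        onsets = []
        for rho in (1.0, 8.0):
            params = ControllerParams(reactivity=rho, safety=1.2)
            traj = integrate_trajectory(start, nominal, params, obstacle)
            onsets.append(deviation_onset(traj, start, nominal.target))
        assert onsets[1] < onsets[0]


class TestImpenetrabilityProperty:
    def test_random_draws(self):
        obstacle, nominal, start = default_workspace()
        rng = np.random.default_rng(42)
        n = 50
        rho = rng.uniform(1, 8, n)
        s = rng.uniform(1.0, 1.5, n)
        _, comfort, min_gamma, completed = simulate_costs(rho, s, nominal, obstacle, start)
        assert np.all(min_gamma >= 1 - 1e-3)
        assert np.all(comfort >= 0)
        assert completed.all()


def test_surface_distance_sign():
    obstacle, _, _ = default_workspace()
    assert surface_distance(np.array([0.5, 0.0, 0.0]), obstacle) > 0
    assert surface_distance(np.array([0.01, 0.0, 0.0]), obstacle) < 0
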