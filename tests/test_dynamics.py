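"""Unit and property tests for the bistable node/network dynamics."""

import numpy as np
import pytest

from ictonet import (
    CouplingMatrix,
    NodeParameters,
    NoiseSpec,
    SimulationConfig,
    SimulationDivergedError,
    drift,
    radial_equilibria,
    sample_node_frequencies,
    simulate_network,
)
from ictonet.dynamics import _integrate_batch, stable_limit_cycle_radius


def brute_force_radial_equilibria(params, n_scan=10_000, r_max=2.0):
    """Oracle: scan the sign of Re(conj(z) * drift(z)) over radii in (0, r_max)."""
    radii = np.linspace(1e-6, r_max, n_scan)
    z = radii.astype(complex)
    flow = np.real(np.conj(z) * drift(z, params))
    out = []
    sign = np.sign(flow)
    # origin: stable iff the flow just above 0 points inward
    out.append((0.0, "stable" if sign[0] < 0 else "unstable"))
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    for k in crossings:
        r = 0.5 * (radii[k] + radii[k + 1])
        out.append((r, "stable" if sign[k] > 0 else "unstable"))
    return out


class TestDrift:
    def test_origin_is_equilibrium(self, params):
        assert drift(0j, params) == 0j

    def test_hand_evaluated_point(self, params):
        # (-1 + 2 - 0.9)*1 + i*1*1
        assert drift(1 + 0j, params) == pytest.approx(0.1 + 1.0j)

    def test_purely_tangential_on_limit_cycle(self, params):
        r = stable_limit_cycle_radius(params)
        z = r * np.exp(1j * 0.7)
        radial_component = np.real(np.conj(z) * drift(z, params))
        assert abs(radial_component) < 1e-9

    def test_coupling_input_is_added(self, params):
        assert drift(1 + 0j, params, coupling_input=0.5j) == pytest.approx(0.1 + 1.5j)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(ValueError):
            drift(complex(np.nan, 0), params)


class TestRadialEquilibria:
    def test_bistable_operating_point(self, params):
        eq = radial_equilibria(params)
        radii = [r for r, _ in eq]
        stabilities = [s for _, s in eq]
        assert radii == pytest.approx([0.0, np.sqrt(0.683772), np.sqrt(1.316228)], abs=1e-5)
        assert stabilities == ["stable", "unstable", "stable"]

    def test_unstable_origin_single_cycle(self):
        eq = radial_equilibria(NodeParameters(a=-1, b=2, c=0.5))
        assert eq[0] == (0.0, "unstable")
        cycles = [s for r, s in eq if r > 0]
        assert cycles == ["stable"]

    def test_monostable_origin(self):
        eq = radial_equilibria(NodeParameters(a=-1, b=0, c=-1))
        assert eq == [(0.0, "stable")]

    def test_degenerate_quartic_rejected(self):
        with pytest.raises(ValueError):
            radial_equilibria(NodeParameters(a=0, b=1, c=-1))

    @pytest.mark.parametrize(
        "p",
        [
            NodeParameters(-1, 2, -0.9),
            NodeParameters(-1, 2, 0.5),
            NodeParameters(-1, 0, -1),
            NodeParameters(-0.5, 1.5, -0.8),
            NodeParameters(-2.0, 3.0, -1.0),
        ],
    )
    def test_agrees_with_sign_scan_oracle(self, p):
        expected = brute_force_radial_equilibria(p)
        got = radial_equilibria(p)
        assert len(got) == len(expected)
        for (r_got, s_got), (r_exp, s_exp) in zip(got, expected):
            assert r_got == pytest.approx(r_exp, abs=1e-3)
            assert s_got == s_exp


class TestFrequencies:
    def test_degenerate_interval(self):
        freqs = sample_node_frequencies(1.0, 0.0, 19, seed=0)
        assert np.all(freqs == 1.0)

    def test_support(self):
        freqs = sample_node_frequencies(1.0, 0.2, 1000, seed=1)
        assert np.all((freqs >= 0.8) & (freqs <= 1.2))

    def test_mean_matches_uniform_clt_bound(self):
        n = 100_000
        freqs = sample_node_frequencies(1.0, 0.2, n, seed=2)
        tol = 3 * (0.2 / np.sqrt(3)) / np.sqrt(n)
        assert abs(freqs.mean() - 1.0) < tol

    def test_reproducible(self):
        a = sample_node_frequencies(1.0, 0.2, 10, seed=3)
        b = sample_node_frequencies(1.0, 0.2, 10, seed=3)
        np.testing.assert_array_equal(a, b)


class TestSimulateNetwork:
    def test_steady_state_stays_at_origin_without_noise(self, params, quiet, single_node):
        traj = simulate_network(
            params, single_node, quiet,
            SimulationConfig(dt=0.005, duration=10.0, init_mode="at_steady_state"),
        )
        assert np.all(traj.states == 0)

    def test_limit_cycle_radius_preserved(self, params, quiet, single_node):
        """The discrete orbit tracks the analytic limit-cycle radius.

        The first-order scheme carries an O(dt) outward radius bias of about
        r*omega^2*dt / (2*|g'(u)|), so the 1e-3 check runs at dt = 0.002 and
        the bias itself is checked to shrink roughly linearly in dt.
        """
        r = stable_limit_cycle_radius(params)
        devs = {}
        for dt in (0.004, 0.002):
            traj = simulate_network(
                params, single_node, quiet,
                SimulationConfig(dt=dt, duration=100.0, init_mode="on_limit_cycle"),
                frequencies=[1.0],
            )
            devs[dt] = np.max(np.abs(np.abs(traj.states) - r))
        assert devs[0.002] < 1e-3
        assert 1.5 < devs[0.004] / devs[0.002] < 3.0

    def test_zero_coupling_decouples_into_single_nodes(self, params):
        """With G = 0 and per-node noise streams, node 0 of a 2-node run
        reproduces the corresponding single-node run exactly."""
        noise = NoiseSpec(sigma=0.3, seed=11)
        config = SimulationConfig(dt=0.01, duration=5.0, init_mode="at_steady_state")
        pair = simulate_network(
            params, CouplingMatrix.uncoupled(2), noise, config, frequencies=[1.05, 0.95]
        )
        solo = simulate_network(
            params, CouplingMatrix.uncoupled(1), noise, config, frequencies=[1.05]
        )
        np.testing.assert_array_equal(pair.states[0], solo.states[0])

    def test_deterministic_given_seeds(self, params):
        coupling = CouplingMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        noise = NoiseSpec(sigma=0.2, seed=5)
        config = SimulationConfig(dt=0.01, duration=5.0, seed=9)
        a = simulate_network(params, coupling, noise, config)
        b = simulate_network(params, coupling, noise, config)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.node_frequencies, b.node_frequencies)

    def test_divergence_guard_trips_on_unstable_parameters(self):
        # a > 0 makes the drift expansive at large radius
        bad = NodeParameters(a=1.0, b=0.0, c=1.0, omega=1.0)
        with pytest.raises(SimulationDivergedError) as err:
            simulate_network(
                bad, CouplingMatrix.uncoupled(1), NoiseSpec(sigma=0.0),
                SimulationConfig(dt=0.01, duration=50.0, init_mode="random_disk",
                                 init_radius=1.5, seed=1),
            )
        assert err.value.step >= 1

    def test_frequency_shape_validated(self, params, quiet, single_node, short_config):
        with pytest.raises(ValueError):
            simulate_network(params, single_node, quiet, short_config, frequencies=[1.0, 2.0])


class TestIntegratorProperties:
    def _endpoint(self, params, z0, dt, duration=10.0):
        n_steps = int(round(duration / dt))
        final, _, _ = _integrate_batch(
            np.array([[z0]]), np.zeros((1, 1)), params, np.array([params.omega]),
            0.0, dt, n_steps, np.random.default_rng(0),
        )
        return final[0, 0]

    def test_rotational_symmetry(self, params):
        """Rotating the initial condition rotates the whole trajectory."""
        theta = 0.9
        rot = np.exp(1j * theta)
        n_steps = int(round(10.0 / 0.005))
        _, hist_a, _ = _integrate_batch(
            np.array([[0.6 + 0.2j]]), np.zeros((1, 1)), params,
            np.array([1.0]), 0.0, 0.005, n_steps, np.random.default_rng(0), record=True,
        )
        _, hist_b, _ = _integrate_batch(
            np.array([[(0.6 + 0.2j) * rot]]), np.zeros((1, 1)), params,
            np.array([1.0]), 0.0, 0.005, n_steps, np.random.default_rng(0), record=True,
        )
        assert np.max(np.abs(hist_a[0, 0] * rot - hist_b[0, 0])) < 1e-9

    def test_first_order_convergence(self, params):
        """Halving dt roughly halves the endpoint error of the noise-free scheme."""
        ref = self._endpoint(params, 0.5 + 0.0j, dt=0.0005)
        errors = [abs(self._endpoint(params, 0.5 + 0.0j, dt=dt) - ref) for dt in (0.016, 0.008, 0.004)]
        ratios = [errors[i] / errors[i + 1] for i in range(len(errors) - 1)]
        for r in ratios:
            assert 1.5 < r < 3.0

    def test_no_basin_crossing_without_noise(self, params):
        """Noise-free trajectories converge to the attractor of their basin."""
        unstable = np.sqrt(0.683772)
        below = self._endpoint(params, (unstable - 0.05) + 0j, dt=0.005, duration=200.0)
        above = self._endpoint(params, (unstable + 0.05) + 0j, dt=0.005, duration=200.0)
        assert abs(below) < 1e-3
        # converges to the discrete cycle, offset O(dt) from the analytic radius
        assert abs(abs(above) - stable_limit_cycle_radius(params)) < 3e-3
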