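"""Stuart-Landau LSA, criticality search, forward simulation and power."""

import math

import numpy as np
import pytest

import connwave as cw
from connwave import arrange, normalize as nz, stuartlandau as sl

from conftest import nc_from_matrix


def single_node():
    return cw.Connectome(np.zeros((1, 1)), np.zeros((1, 1)))


class TestLSA:
    def test_uncoupled_closed_form(self):
        nc = nc_from_matrix(np.zeros((4, 4)))
        res = sl.lsa_normalized(nc, r=-1.0, omega=3.0)
        np.testing.assert_allclose(res.eigenvalues.real, -1.0, atol=1e-12)
        np.testing.assert_allclose(np.sort(np.abs(res.eigenvalues.imag)), 3.0)

    def test_two_node_real_parts(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        res = sl.lsa_normalized(nc_from_matrix(W), r=0.0, omega=1.0)
        np.testing.assert_allclose(
            np.sort(res.eigenvalues.real), [-0.5, -0.5, 0.5, 0.5], atol=1e-12
        )

    def test_real_parts_match_symmetric_eigensolver_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            W = rng.normal(size=(n, n))
            W = np.triu(W, 1) + np.triu(W, 1).T
            nc = nc_from_matrix(W)
            r = float(rng.normal())
            res = sl.lsa_normalized(nc, r=r, omega=10.0)
            mu = np.linalg.eigvalsh(W)
            expected = np.sort(np.repeat(r + mu, 2))
            assert np.abs(np.sort(res.eigenvalues.real) - expected).max() < 1e-9

    def test_leading_sign_pattern_matches_top_eigenvector(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            W = rng.normal(size=(10, 10))
            W = np.triu(W, 1) + np.triu(W, 1).T
            nc = nc_from_matrix(W)
            res = sl.lsa_normalized(nc, r=0.0, omega=5.0)
            _, U = np.linalg.eigh(W)
            v = U[:, -1]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            np.testing.assert_array_equal(
                np.sign(res.leading_eigenvector), np.sign(v)
            )

    def test_asymmetric_matrix_rejected(self):
        nc = nc_from_matrix(np.zeros((3, 3)))
        object.__setattr__(nc, "wave_weights", np.array(
            [[0, 1.0, 0], [0, 0, 0], [0, 0, 0]]
        ))
        with pytest.raises(ValueError, match="symmetric"):
            sl.lsa_normalized(nc, 0.0, 1.0)


class TestCriticality:
    def test_uncoupled_critical_r_near_zero(self):
        nc = nc_from_matrix(np.zeros((3, 3)))
        r = sl.find_critical_r(nc, omega=5.0)
        assert 0 < r <= 1e-6

    def test_two_node_closed_form(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        r = sl.find_critical_r(nc_from_matrix(W), omega=5.0)
        assert r == pytest.approx(-0.5, abs=1e-6)
        assert r > -0.5

    def test_random_matrices_match_eigensolver(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            W = rng.normal(size=(8, 8))
            W = np.triu(W, 1) + np.triu(W, 1).T
            nc = nc_from_matrix(W)
            r = sl.find_critical_r(nc, omega=10.0)
            mu_max = np.linalg.eigvalsh(W)[-1]
            assert abs(r + mu_max) <= 1e-6

    def test_regime_offsets(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        nc = nc_from_matrix(W)
        rc = sl.r_for_regime(nc, 5.0, "critical")
        assert sl.r_for_regime(nc, 5.0, "subcritical") == pytest.approx(rc - 0.2)
        assert sl.r_for_regime(nc, 5.0, "supercritical") == pytest.approx(rc + 0.2)


class TestSimulation:
    def test_damped_focus_decays(self):
        p = sl.SLParams(r=-0.5, omega_rad_s=2 * math.pi * 10, G=0.0, D=0.0,
                        dt=1e-3, duration=20.0)
        traj = sl.simulate_full(single_node(), p, 5.0,
                                initial_states=np.array([1.0 + 0.0j]))
        assert abs(traj.states[0, -1]) < 1e-3

    @pytest.mark.parametrize("r0", [0.04, 0.25, 1.0])
    def test_limit_cycle_amplitude_sqrt_r(self, r0):
        p = sl.SLParams(r=r0, omega_rad_s=2 * math.pi * 10, G=0.0, D=0.0,
                        dt=5e-4, duration=max(20.0, 4.0 / r0))
        traj = sl.simulate_full(
            single_node(), p, 5.0,
            initial_states=np.array([0.9 * math.sqrt(r0) + 0.0j]),
        )
        amp = abs(traj.states[0, -1])
        assert amp == pytest.approx(math.sqrt(r0), rel=0.01)

    def test_two_node_half_period_delay_anti_phase(self):
        l_mm = 250.0  # tau = 50 ms = half period at 10 Hz, v = 5 m/s
        W = np.array([[0.0, 0.4], [0.4, 0.0]])
        L = np.array([[0.0, l_mm], [l_mm, 0.0]])
        c = cw.Connectome(W, L)
        p = sl.SLParams(r=0.25, omega_rad_s=2 * math.pi * 10, G=1.0, D=0.0,
                        dt=1e-3, duration=10.0)
        x0 = np.array([0.5 + 0j, 0.5 * np.exp(1j * 1.5)])
        traj = sl.simulate_full(c, p, 5.0, initial_states=x0)
        k0 = traj.times.size // 2
        dphi = np.angle(
            np.exp(1j * (np.angle(traj.states[0, k0:]) -
                         np.angle(traj.states[1, k0:])))
        ).mean()
        assert abs(abs(dphi) - math.pi) < 0.2
        arr = sl.phase_arrangement_from_data(traj)
        assert arr.signs[0] != arr.signs[1]

    def test_divergence_reported_with_time(self):
        # strongly supercritical positive feedback without saturation from
        # large G blows up
        W = np.array([[0.0, 5.0], [5.0, 0.0]])
        L = np.array([[0.0, 10.0], [10.0, 0.0]])
        c = cw.Connectome(W, L)
        p = sl.SLParams(r=2.0, omega_rad_s=1.0, G=200.0, D=0.0, dt=0.005,
                        duration=30.0)
        with pytest.raises(FloatingPointError, match="t ="):
            sl.simulate_full(c, p, 5.0, initial_states=np.array([1.0 + 0j, 1.0 + 0j]))

    def test_seeded_noise_reproducible(self):
        p = sl.SLParams(r=0.1, omega_rad_s=10.0, G=0.0, D=1e-4, dt=1e-3,
                        duration=2.0, seed=4)
        a = sl.simulate_full(single_node(), p, 5.0)
        b = sl.simulate_full(single_node(), p, 5.0)
        np.testing.assert_array_equal(a.states, b.states)

    def test_dt_cap_enforced(self):
        with pytest.raises(ValueError):
            sl.SLParams(r=0.0, omega_rad_s=1.0, dt=0.01)
        assert sl.recommended_dt(40.0, 9.0) <= 0.005


class TestNodePower:
    def _tone_trajectory(self, amps, f0=10.0, duration=4.0, dt=1e-3):
        t = np.arange(int(duration / dt) + 1) * dt
        states = np.array([a * np.exp(1j * 2 * math.pi * f0 * t) for a in amps])
        p = sl.SLParams(r=0.1, omega_rad_s=2 * math.pi * f0, dt=dt,
                        duration=duration)
        return sl.OscillatorTrajectory(times=t, states=states, params=p,
                                       model="normalized_instantaneous")

    def test_pure_tone_power_scales_with_amplitude_squared(self):
        traj = self._tone_trajectory([1.0, 2.0, 3.0])
        p = sl.node_power(traj, 10.0)
        np.testing.assert_allclose(p / p[0], [1.0, 4.0, 9.0], rtol=1e-6)

    def test_zero_signal_zero_power(self):
        traj = self._tone_trajectory([0.0, 1.0])
        assert sl.node_power(traj, 10.0)[0] == 0.0

    def test_noisy_tone_within_ten_percent(self):
        rng = np.random.default_rng(0)
        traj = self._tone_trajectory([1.0, 2.0], duration=8.0)
        noisy = traj.states + 0.05 * (
            rng.standard_normal(traj.states.shape)
            + 1j * rng.standard_normal(traj.states.shape)
        )
        traj2 = sl.OscillatorTrajectory(times=traj.times, states=noisy,
                                        params=traj.params,
                                        model=traj.model)
        p = sl.node_power(traj2, 10.0)
        assert p[1] / p[0] == pytest.approx(4.0, rel=0.1)

    def test_short_window_rejected(self):
        traj = self._tone_trajectory([1.0], duration=0.5)
        with pytest.raises(ValueError, match="10 periods"):
            sl.node_power(traj, 10.0)

    def test_bandpower_method_agrees_on_tone_ranking(self):
        traj = self._tone_trajectory([1.0, 2.0])
        a = sl.node_power(traj, 10.0, method="periodogram")
        b = sl.node_power(traj, 10.0, method="bandpower")
        assert (np.argsort(a) == np.argsort(b)).all()


class TestPhaseArrangementFromData:
    def _traj(self, states, dt=1e-3):
        t = np.arange(states.shape[1]) * dt
        p = sl.SLParams(r=0.1, omega_rad_s=10.0, dt=dt, duration=t[-1])
        return sl.OscillatorTrajectory(times=t, states=states, params=p,
                                       model="normalized_instantaneous")

    def test_identical_trajectories_all_plus(self):
        t = np.arange(2000) * 1e-3
        x = np.exp(1j * 2 * math.pi * 5 * t)
        traj = self._traj(np.stack([x, x, x]))
        np.testing.assert_array_equal(
            sl.phase_arrangement_from_data(traj).signs, [1, 1, 1]
        )

    def test_opposite_signal_is_anti_phase(self):
        t = np.arange(2000) * 1e-3
        x = np.exp(1j * 2 * math.pi * 5 * t)
        traj = self._traj(np.stack([x, -x]))
        arr = sl.phase_arrangement_from_data(traj)
        assert arr.signs[0] * arr.signs[1] == -1

    def test_unlocked_node_warns(self):
        rng = np.random.default_rng(1)
        t = np.arange(2000) * 1e-3
        x = np.exp(1j * 2 * math.pi * 5 * t)
        noise = np.exp(1j * rng.uniform(-math.pi, math.pi, t.size))
        traj = self._traj(np.stack([x, noise]))
        with pytest.warns(UserWarning, match="not phase-locked"):
            sl.phase_arrangement_from_data(traj)


class TestCorrelation:
    def test_power_proportional_to_metric_gives_unit_correlation(self):
        power = np.array([1.0, 2.0, 3.0, 4.0])
        tab = sl.correlate_metrics_with_power(power, {"C0": 2.5 * power})
        assert tab.loc["C0", "r"] == pytest.approx(1.0)

    def test_permuted_metric_decorrelates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=68)
        perm = rng.permutation(68)
        tab = sl.correlate_metrics_with_power(x, {"C0": x, "perm": x[perm]})
        assert abs(tab.loc["perm", "r"]) < 0.2

    def test_constant_vector_flagged_undefined(self):
        tab = sl.correlate_metrics_with_power(
            np.ones(5), {"C0": np.arange(5.0)}
        )
        assert not tab.loc["C0", "defined"]
        assert math.isnan(tab.loc["C0", "r"])

    def test_wave_metric_beats_particle_null_at_alpha(self):
        """Eigenvector-arranged strength predicts the critical-mode pattern
        better than the signed in-strength null at 10 Hz."""
        wins = 0
        n_seeds = 6
        for s in range(n_seeds):
            c = cw.generate_synthetic_connectome(68, density=0.3, seed=500 + s)
            c = c.with_weights(
                np.where(c.weights > 0,
                         np.maximum(np.log(np.maximum(c.weights, 1.0)), 0), 0),
                "log",
            )
            nc = nz.wave_couplings(c, 10.0, 5.0)
            om = 2 * math.pi * 10
            lsa = sl.lsa_normalized(nc, sl.find_critical_r(nc, om), om)
            eig_arr = arrange.eigenvector_arrangement(nc)
            power = sl.lsa_power_pattern(lsa)
            tab = sl.correlate_metrics_with_power(
                power,
                {
                    "S_eig": nz.spectral_strength(nc, eig_arr),
                    "C0": nz.particle_strength(c, eig_arr),
                },
                arrangement=eig_arr,
            )
            wins += tab.loc["S_eig", "r"] > tab.loc["C0", "r"]
        assert wins >= n_seeds - 1

    def test_critical_power_ranking_tracks_leading_eigenvector(self):
        """Simulated power at criticality follows |v| of the leading mode."""
        from scipy.stats import spearmanr

        c = cw.generate_synthetic_connectome(12, density=0.5, seed=21)
        c = c.with_weights(c.weights / np.abs(c.weights).sum(1).max(), "raw")
        nc = nz.wave_couplings(c, 10.0, 5.0)
        om = 2 * math.pi * 10
        r_crit = sl.find_critical_r(nc, om)
        lsa = sl.lsa_normalized(nc, r_crit, om)
        p = sl.SLParams(r=r_crit, omega_rad_s=om, G=1.0, D=1e-6, dt=1e-3,
                        duration=40.0, seed=2)
        traj = sl.simulate_normalized(nc, p)
        power = sl.node_power(traj, 10.0)
        rho = spearmanr(power, np.abs(lsa.leading_eigenvector)).statistic
        assert rho > 0.9
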