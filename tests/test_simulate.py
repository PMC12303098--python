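import numpy as np
import pytest

from tipcast import _kernels as K
from tipcast import simulate as sim

from conftest import make_system


class TestRedNoise:
    @pytest.mark.parametrize("phi", [0.0, 0.7, -0.5])
    def test_ar1_moments(self, phi):
        n = 100_000
        eta = sim.gen_red_noise(phi, 2.0, n, rng_seed=1)
        ac1 = np.corrcoef(eta[:-1], eta[1:])[0, 1]
        assert ac1 == pytest.approx(phi, abs=3.0 / np.sqrt(n) + 0.01)
        assert eta.std() == pytest.approx(2.0, rel=0.03)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_red_noise(1.0, 1.0, 10, 0)


class TestSimulateRamp:
    def test_noise_free_linear_decay_matches_closed_form(self):
        ramp = sim.RampSpec(mu0=0.0, rate=1e-3, direction=1, mu_terminal=0.005)
        traj = sim.simulate_ramp(lambda s, mu: -s, [1.0],
                                 ramp, sim.NoiseSpec(kind="none"), burn_in=0.0)
        expect = np.exp(-traj.times)
        assert np.abs(traj.states[:, 0] - expect).max() < 0.05  # Euler O(dt)
        assert np.all(np.diff(traj.states[:, 0]) < 0)

    def test_mu_values_follow_affine_law_exactly(self):
        ramp = sim.RampSpec(mu0=1.0, rate=0.01, direction=-1, mu_terminal=0.8)
        traj = sim.simulate_ramp(lambda s, mu: -s, [0.5], ramp,
                                 sim.NoiseSpec(kind="white", sigma=0.01),
                                 burn_in=1.0, rng_seed=3)
        expect = 1.0 - 0.01 * 0.01 * np.arange(1, len(traj.times) + 1)
        assert np.array_equal(traj.mu_values, expect)

    def test_ou_stationary_variance(self):
        # dx = -x dt + sigma dW at fixed mu: var = sigma^2 / 2
        ramp = sim.RampSpec(mu0=0.0, rate=1e-7, direction=1, mu_terminal=0.0002)
        traj = sim.simulate_ramp(lambda s, mu: -s, [0.0], ramp,
                                 sim.NoiseSpec(kind="white", sigma=0.2),
                                 burn_in=20.0, rng_seed=5)
        var = traj.states[:, 0].var()
        assert var == pytest.approx(0.2**2 / 2, rel=0.15)

    def test_sigma_zero_white_is_bit_identical_to_euler_twin(self):
        ramp = sim.RampSpec(mu0=0.0, rate=1e-3, direction=1, mu_terminal=0.01)
        t_white = sim.simulate_ramp(lambda s, mu: -s + mu, [1.0], ramp,
                                    sim.NoiseSpec(kind="white", sigma=0.0),
                                    rng_seed=1)
        t_none = sim.simulate_ramp(lambda s, mu: -s + mu, [1.0], ramp,
                                   sim.NoiseSpec(kind="none"), rng_seed=2)
        assert np.array_equal(t_white.states, t_none.states)

    def test_divergence_truncates_with_flag(self):
        ramp = sim.RampSpec(mu0=0.0, rate=1e-3, direction=1, mu_terminal=1.0)
        traj = sim.simulate_ramp(lambda s, mu: s, [1.0], ramp,
                                 sim.NoiseSpec(kind="none"),
                                 burn_in=0.0, divergence_bound=100.0)
        assert traj.diverged
        assert len(traj.times) < 1e4


class TestRecoveryRateAndTipping:
    def test_constant_lambda_for_linear_field(self):
        ramp = sim.RampSpec(mu0=0.0, rate=1e-3, direction=1, mu_terminal=0.01)
        traj = sim.simulate_ramp(lambda s, mu: np.array([-2.0, -1.0]) * s,
                                 [1.0, 1.0], ramp, sim.NoiseSpec(kind="none"),
                                 burn_in=0.0)
        lams = sim.recovery_rate_series(
            lambda s, mu: np.diag([-2.0, -1.0]), traj, stride=10)
        assert np.allclose(lams, -1.0)

    def test_fold_branch_lambda_tracks_analytic_value(self, fold_nf):
        # dx = a1 - x^2 settled: lambda ~ -2 sqrt(a1) under a slow ramp
        mus, lams, status = K.ramp_poly_lambda(
            fold_nf.a_coeffs, fold_nf.b_coeffs, 0, 1.0, 0.0, 1.0, -1e-3, 0.2,
            0.01, 10, 1e6, 0)
        expect = np.maximum(-2.0 * np.sqrt(mus), -1.0)
        assert np.abs(lams - expect).max() < 0.02

    def test_interpolated_crossing_and_no_crossing(self):
        assert sim.locate_tipping([-0.2, -0.1, 0.1], [0, 1, 2]) == pytest.approx(1.5)
        assert sim.locate_tipping([-1.0, -2.0], [0, 1]) is None
        with pytest.raises(ValueError):
            sim.locate_tipping([], [])

    def test_crossing_invariant_under_positive_scaling_of_lambda(self):
        rng = np.random.default_rng(0)
        lam = np.linspace(-1, 0.3, 40) + 0.01 * rng.standard_normal(40)
        mu = np.linspace(0, 1, 40)
        base = sim.locate_tipping(lam, mu)
        for c in (0.1, 3.7, 250.0):
            assert sim.locate_tipping(c * lam, mu) == pytest.approx(base, rel=1e-12)

    def test_fold_delay_follows_two_thirds_power_law(self):
        # canonical fold dx = mu + x^2 ramped upward: the lambda crossing
        # overshoots mu = 0 as 1.0188 (rate)^(2/3)
        A = np.zeros(10); A[0] = -1.0; A[3] = 1.0
        B = np.zeros(10); B[2] = -1.0
        rates = np.array([1e-4, 2e-4, 4e-4, 8e-4])
        over = []
        for r in rates:
            mus, lams, _ = K.ramp_poly_lambda(A, B, 0, -1.0, 0.0, -1.0, r,
                                              0.5, 0.01, 2, 1e6, 0)
            over.append(sim.locate_tipping(lams, mus))
        over = np.array(over)
        ratio = over[3] / over[0]
        assert ratio == pytest.approx(4.0, rel=0.10)
        slope = np.polyfit(np.log(rates), np.log(over), 1)[0]
        assert slope == pytest.approx(2.0 / 3.0, abs=0.07)


class TestIrregularSampling:
    def _traj(self, n=30_000, mu_c=0.9):
        times = 0.01 * np.arange(1, n + 1)
        mus = np.linspace(0.0, 1.0, n)
        values = np.sin(times) + 0.01 * np.random.default_rng(0).standard_normal(n)
        return times, values, mus, mu_c

    def test_sample_shape_and_window(self):
        t, v, m, mu_c = self._traj()
        rng = np.random.default_rng(1)
        for _ in range(10):
            s = sim.irregular_sample_arrays(t, v, m, mu_c, 1, rng)
            assert len(s.values) == 500
            assert np.all(np.diff(s.times) > 0)
            assert np.all(s.mu_values < mu_c)
            assert 0.01 <= s.relative_distance <= 2.0

    def test_short_pretipping_segment_rejected(self):
        t, v, m, _ = self._traj(n=800)
        with pytest.raises(ValueError):
            sim.irregular_sample_arrays(t, v, m, 2.0, 1, np.random.default_rng(0))

    def test_mu_end_matches_order_statistic_law(self):
        # oracle: mu_end/mu_c is the 500th order statistic of ls uniforms;
        # simulate the law directly and compare empirical quantiles
        t, v, m, mu_c = self._traj()
        rng = np.random.default_rng(2)
        ends = np.array([sim.irregular_sample_arrays(t, v, m, mu_c, 1, rng)
                         .mu_values[-1] for _ in range(400)]) / mu_c
        rng2 = np.random.default_rng(3)
        oracle = []
        for _ in range(4000):
            ls = rng2.integers(505, 1001)
            u = np.sort(rng2.uniform(0, 1, ls))
            oracle.append(u[499])
        qs = np.linspace(0.1, 0.9, 9)
        dq = np.abs(np.quantile(ends, qs) - np.quantile(oracle, qs))
        assert dq.max() < 0.04


class TestTrainingSet:
    def test_empty_library_gives_empty_set(self):
        assert sim.make_training_set([], rng_seed=0) == []

    def test_labels_are_rate_delayed_beyond_static(self, small_library,
                                                   small_corpus):
        by_key = {(r.system_id, r.varied_index, r.direction): r
                  for _, r in small_library}
        for s in small_corpus:
            r = by_key[(s.system_id, s.seeds["varied_index"],
                        s.seeds["direction"])]
            # rate delay pushes the crossing at/past the static bifurcation;
            # Hopf instances may cross marginally early because the
            # trajectory spirals around (not on) the moving equilibrium
            tol = 1e-6 + 0.02 * abs(r.mu_static)
            assert (s.mu_c - r.mu_static) * r.direction > -tol

    def test_instances_are_complete_and_tagged(self, small_corpus):
        assert len(small_corpus) == 120
        for s in small_corpus:
            assert len(s.values) == 500
            assert s.noise_kind in ("white", "red")
            assert s.bif_type in ("fold", "hopf", "transcritical")
            assert s.rate > 0
            assert 0.01 <= s.relative_distance <= 2.0

    def test_reproducible_given_seed(self, small_library):
        a = sim.make_training_set(small_library, rng_seed=5, n_instances=10)
        b = sim.make_training_set(small_library, rng_seed=5, n_instances=10)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)
            assert x.mu_c == y.mu_c
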