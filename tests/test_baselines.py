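import numpy as np
import pytest

from tipcast import baselines as B


def ar1(phi, n, rng, sd=1.0):
    e = rng.normal(0, sd, n)
    out = np.empty(n)
    out[0] = e[0]
    for t in range(1, n):
        out[t] = phi * out[t - 1] + e[t]
    return out


def ou_red(lam_discrete, phi, n, rng):
    """x_{t+1} = a x_t + eta_t with AR(1) driving noise eta."""
    eta = ar1(phi, n, rng)
    x = np.empty(n)
    x[0] = 0.0
    for t in range(1, n):
        x[t] = lam_discrete * x[t - 1] + eta[t - 1]
    return x


class TestDegenerateFingerprinting:
    def test_white_noise_indicator_near_zero(self):
        rng = np.random.default_rng(0)
        ind = B.degenerate_fingerprinting(rng.normal(0, 1, 1000),
                                          window_frac=0.5, step=50)
        assert abs(np.nanmean(ind.indicator_values)) < 0.05
        assert ind.critical_value == 1.0

    def test_stationary_ar1_recovers_phi(self):
        rng = np.random.default_rng(1)
        x = ar1(0.8, 6000, rng)
        ind = B.degenerate_fingerprinting(x, window_frac=0.5, step=250)
        assert np.nanmean(ind.indicator_values) == pytest.approx(0.8, abs=0.04)

    def test_multivariate_projects_onto_leading_mode(self):
        rng = np.random.default_rng(2)
        mode = ar1(0.9, 4000, rng)
        X = np.column_stack([2.0 * mode + rng.normal(0, 0.1, 4000),
                             -1.0 * mode + rng.normal(0, 0.1, 4000)])
        ind = B.degenerate_fingerprinting(X, window_frac=0.5, step=500)
        assert np.nanmean(ind.indicator_values) == pytest.approx(0.9, abs=0.05)

    def test_ramped_ou_indicator_rises_toward_one(self):
        # lambda ramps toward 0: theoretical AC = exp(lambda dt) -> 1
        rng = np.random.default_rng(3)
        n = 8000
        lam = np.linspace(-1.0, -0.02, n)
        dt = 0.5
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = x[t - 1] + lam[t] * x[t - 1] * dt + 0.1 * np.sqrt(dt) * rng.normal()
        mu = np.linspace(0, 1, n)
        ind = B.degenerate_fingerprinting(x, window_frac=0.25, mu_values=mu,
                                          step=200)
        from scipy.stats import spearmanr
        rho = spearmanr(ind.window_centers, ind.indicator_values).statistic
        assert rho > 0.9

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            B.degenerate_fingerprinting(np.zeros(40), window_frac=0.5)


class TestBBLambda:
    def test_ou_white_noise_recovers_lambda(self):
        rng = np.random.default_rng(4)
        a = np.exp(-0.5)  # lambda = -0.5 at dt = 1
        x = ou_red(a, 0.0, 40_000, rng)
        ind = B.bb_lambda(x, dt=1.0, window_frac=0.5, step=4000)
        assert np.nanmean(ind.indicator_values) == pytest.approx(-0.5, abs=0.05)
        assert ind.critical_value == 0.0

    def test_red_noise_bias_removed_relative_to_naive(self):
        rng = np.random.default_rng(5)
        a = np.exp(-0.5)
        bb_means, naive_means = [], []
        for _ in range(30):
            x = ou_red(a, 0.5, 6000, rng)
            bb_means.append(np.nanmean(
                B.bb_lambda(x, 1.0, 0.5, step=1500).indicator_values))
            naive_means.append(np.nanmean(
                B.naive_lambda(x, 1.0, 0.5, step=1500).indicator_values))
        bb_bias = abs(np.mean(bb_means) + 0.5)
        naive_bias = abs(np.mean(naive_means) + 0.5)
        # the naive lag-1 rate is biased upward by the red noise; the joint
        # AR(2) fit removes most of it
        sigma = np.std(bb_means) / np.sqrt(len(bb_means))
        assert naive_bias - bb_bias > 3 * sigma
        assert bb_bias < naive_bias / 2

    def test_white_noise_limit_matches_naive(self):
        rng = np.random.default_rng(6)
        x = ou_red(np.exp(-0.5), 0.0, 30_000, rng)
        bb = np.nanmean(B.bb_lambda(x, 1.0, 0.5, step=3000).indicator_values)
        naive = np.nanmean(B.naive_lambda(x, 1.0, 0.5, step=3000).indicator_values)
        assert bb == pytest.approx(naive, abs=0.06)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            B.bb_lambda(np.zeros(50), dt=1.0, window_frac=0.5)


class TestDEV:
    def test_linear_map_dominant_eigenvalue(self):
        rng = np.random.default_rng(7)
        x = ar1(0.9, 6000, rng)
        ind = B.dev_series(x, embed_dim=1, window_frac=0.5, step=500)
        assert np.nanmean(ind.indicator_values) == pytest.approx(0.9, abs=0.03)
        assert ind.critical_value == 1.0

    def test_damped_rotation_modulus(self):
        # damped noisy rotation in delay coordinates: x_t = 2 r cos(w) x_{t-1}
        # - r^2 x_{t-2} + eps has eigenvalues r e^{+-iw}; the DEV modulus
        # from a 2-dimensional embedding must recover r
        rng = np.random.default_rng(8)
        r, w = 0.9, 0.7
        phi1, phi2 = 2 * r * np.cos(w), -r * r
        n = 8000
        x = np.zeros(n)
        e = rng.normal(0, 1, n)
        for t in range(2, n):
            x[t] = phi1 * x[t - 1] + phi2 * x[t - 2] + e[t]
        ind = B.dev_series(x, embed_dim=2, window_frac=0.5, step=1000)
        assert np.nanmean(ind.indicator_values) == pytest.approx(r, abs=0.03)

    def test_smap_weighting_consistent_on_linear_map(self):
        rng = np.random.default_rng(9)
        x = ar1(0.85, 700, rng)
        glob = B.dev_series(x, embed_dim=1, window_frac=0.5, step=200)
        local = B.dev_series(x, embed_dim=1, theta=1.0, window_frac=0.5,
                             step=200)
        assert np.nanmean(local.indicator_values) == pytest.approx(
            np.nanmean(glob.indicator_values), abs=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            B.dev_series(np.ones(500))


class TestAffineInvariance:
    def test_ac1_and_dev_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(10)
        x = ar1(0.7, 3000, rng)
        y = -5.0 * x + 11.0
        for fn in (lambda s: B.degenerate_fingerprinting(s, 0.5, step=500),
                   lambda s: B.dev_series(s, embed_dim=1, window_frac=0.5,
                                          step=500)):
            a = fn(x).indicator_values
            b = fn(y).indicator_values
            assert np.allclose(a, b, atol=1e-8)


class TestExtrapolation:
    def test_line_through_two_points(self):
        ind = B.IndicatorSeries(np.array([0.0, 1.0, 2.0]),
                                np.array([-1.0, -0.75, -0.5]),
                                "bb_lambda", 0.0, 0.5)
        res = B.extrapolate_crossing(ind)
        assert res.mu_hat == pytest.approx(4.0, abs=1e-9)
        assert res.candidates["linear"]["mu"] == pytest.approx(4.0)

    def test_exact_parabola_recovered(self):
        mu = np.linspace(-1, 1, 25)
        ind = B.IndicatorSeries(mu, mu**2 - 4.0, "ac1", 0.0, 0.5)
        res = B.extrapolate_crossing(ind)
        assert res.selected == "quadratic"
        assert res.mu_hat == pytest.approx(2.0, abs=1e-8)

    def test_no_forward_crossing_flags_failure(self):
        mu = np.linspace(0, 1, 20)
        ind = B.IndicatorSeries(mu, -1.0 - mu, "bb_lambda", 0.0, 0.5)
        res = B.extrapolate_crossing(ind)
        assert res.mu_hat is None
        assert res.selected is None

    def test_too_few_points_rejected(self):
        ind = B.IndicatorSeries(np.array([0.0, 1.0]), np.array([-1.0, -0.5]),
                                "ac1", 0.0, 0.5)
        with pytest.raises(ValueError):
            B.extrapolate_crossing(ind)

    def test_ramped_ou_ac1_extrapolation_hits_known_crossing(self):
        # lambda(mu) = -1 + mu declining to 0 at mu_c = 1; observe up to
        # mu_end = 0.7 and extrapolate the lag-1-AC indicator to 1
        rng = np.random.default_rng(11)
        n = 40_000
        dt = 0.5
        mu = np.linspace(0.0, 0.7, n)
        lam = -1.0 + mu
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = x[t - 1] + lam[t] * x[t - 1] * dt + 0.05 * np.sqrt(dt) * rng.normal()
        ind = B.degenerate_fingerprinting(x, window_frac=0.25, mu_values=mu,
                                          step=1000)
        res = B.extrapolate_crossing(ind)
        assert res.mu_hat is not None
        eps = abs(res.mu_hat - 1.0) / abs(0.7 - 1.0)
        assert eps < 0.25
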