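import numpy as np
import pytest

from tipcast import syslib as S
from tipcast import _kernels as K

from conftest import make_system

CUBIC_IDX = [6, 7, 8, 9, 16, 17, 18, 19]


class TestSamplePolysystem:
    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_deterministic_and_structured(self, seed):
        a = S.sample_polysystem(seed)
        b = S.sample_polysystem(seed)
        assert np.array_equal(a.coeffs, b.coeffs)
        assert np.count_nonzero(a.coeffs == 0.0) == 10
        assert all(a.coeffs[i] <= 0 for i in CUBIC_IDX)
        assert np.isfinite(a.coeffs).all()

    def test_nonzero_noncubic_moments_match_standard_normal(self):
        # oracle: mean 0 / variance 1 of the standard normal, 3-sigma bands
        vals = []
        for seed in range(4000):
            c = S.sample_polysystem(seed).coeffs
            keep = np.ones(20, bool)
            keep[CUBIC_IDX] = False
            v = c[keep]
            vals.extend(v[v != 0.0])
        vals = np.asarray(vals)
        n = len(vals)
        assert abs(vals.mean()) < 3.0 / np.sqrt(n)
        assert abs(vals.var() - 1.0) < 3.0 * np.sqrt(2.0 / n)


class TestFieldAndJacobian:
    def test_zero_and_linear_fields(self):
        zero = make_system({}, {})
        assert S.eval_field(zero, (3.0, -2.0)) == (0.0, 0.0)
        assert np.array_equal(S.eval_jacobian(zero, (1.0, 1.0)), np.zeros((2, 2)))
        lin = make_system({1: 1.0}, {2: -1.0})
        assert S.eval_field(lin, (2.0, 3.0)) == (2.0, -3.0)
        assert np.array_equal(S.eval_jacobian(lin, (5.0, -7.0)),
                              np.array([[1.0, 0.0], [0.0, -1.0]]))

    def test_field_matches_bruteforce_monomial_sum(self):
        rng = np.random.default_rng(3)
        for seed in range(20):
            sys = S.sample_polysystem(seed)
            x, y = rng.uniform(-2, 2, size=2)
            mono = [1, x, y, x**2, x*y, y**2, x**3, x**2*y, x*y**2, y**3]
            fx = sum(c * m for c, m in zip(sys.a_coeffs, mono))
            fy = sum(c * m for c, m in zip(sys.b_coeffs, mono))
            got = S.eval_field(sys, (x, y))
            assert got == pytest.approx((fx, fy), rel=1e-12)

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        h = 1e-6
        for seed in range(50):
            sys = S.sample_polysystem(seed)
            x, y = rng.uniform(-1.5, 1.5, size=2)
            J = S.eval_jacobian(sys, (x, y))
            num = np.empty((2, 2))
            num[:, 0] = (np.array(S.eval_field(sys, (x + h, y))) -
                         np.array(S.eval_field(sys, (x - h, y)))) / (2 * h)
            num[:, 1] = (np.array(S.eval_field(sys, (x, y + h))) -
                         np.array(S.eval_field(sys, (x, y - h)))) / (2 * h)
            scale = max(1.0, np.abs(J).max())
            assert np.abs(J - num).max() / scale < 1e-6

    def test_nonfinite_state_rejected(self):
        sys = make_system({1: 1.0}, {2: -1.0})
        with pytest.raises(ValueError):
            S.eval_field(sys, (np.nan, 0.0))
        with pytest.raises(ValueError):
            S.eval_jacobian(sys, (np.inf, 0.0))


class TestSettle:
    def test_linear_contraction_settles_to_origin(self):
        sys = make_system({1: -1.0}, {2: -1.0})
        eq = S.settle_to_equilibrium(sys, (1.0, 1.0))
        assert eq is not None
        assert eq.state == pytest.approx((0.0, 0.0), abs=1e-8)
        assert eq.residual_norm < 1e-10

    def test_linear_expansion_does_not_converge(self):
        sys = make_system({1: 1.0}, {2: 1.0})
        assert S.settle_to_equilibrium(sys, (1.0, 1.0)) is None

    def test_converged_state_is_a_root_of_the_field(self):
        for seed in (5, 8, 13):
            sys = S.sample_polysystem(seed)
            init = np.random.default_rng(seed).uniform(-1, 1, 2)
            eq = S.settle_to_equilibrium(sys, init)
            if eq is not None:
                fx, fy = S.eval_field(sys, eq.state)
                assert np.hypot(fx, fy) < 1e-8

    def test_invalid_arguments_rejected(self):
        sys = make_system({1: -1.0}, {2: -1.0})
        with pytest.raises(ValueError):
            S.settle_to_equilibrium(sys, (0.0, 0.0), dt=-0.1)


class TestContinuation:
    def test_fold_branch_matches_analytic_eigenvalues(self, fold_nf):
        # branch x* = sqrt(a1), lambda = max(-2 sqrt(a1), -1)
        eq = S.settle_to_equilibrium(fold_nf, (0.5, 0.5))
        branch = S.continue_branch(fold_nf, eq, 0, -1, mu_step=0.01)
        for p in branch:
            x = p.equilibrium.state[0]
            if x > 0.05:  # stable side of the fold (continuation wraps past it)
                assert x == pytest.approx(np.sqrt(p.mu), abs=1e-6)
                assert p.lam == pytest.approx(max(-2 * np.sqrt(p.mu), -1.0), abs=1e-6)
        assert min(p.mu for p in branch) < 0.01  # reached the fold

    def test_transcritical_branch_lambda_equals_mu(self, transcritical_nf):
        eq = S.settle_to_equilibrium(transcritical_nf, (0.2, 0.2))
        branch = S.continue_branch(transcritical_nf, eq, 1, 1, mu_step=0.01)
        for p in branch:
            assert p.equilibrium.state[0] == pytest.approx(0.0, abs=1e-8)
            assert p.lam == pytest.approx(max(p.mu, -1.0), abs=1e-6)

    def test_linear_system_lambda_exact(self):
        sys = make_system({1: -0.5}, {2: -1.0})
        eq = S.settle_to_equilibrium(sys, (0.4, 0.4))
        branch = S.continue_branch(sys, eq, 1, 1, mu_step=0.02)
        for p in branch:
            assert p.lam == pytest.approx(max(p.mu, -1.0), abs=1e-9)

    def test_varied_index_must_be_nonzero(self, fold_nf):
        eq = S.settle_to_equilibrium(fold_nf, (0.5, 0.5))
        with pytest.raises(ValueError):
            S.continue_branch(fold_nf, eq, 5, 1)


class TestDetectBifurcation:
    @pytest.mark.parametrize("which,expected", [
        ("fold_nf", "fold"), ("transcritical_nf", "transcritical"),
        ("hopf_nf", "hopf")])
    def test_normal_forms_classified_with_accurate_location(
            self, which, expected, request):
        sys = request.getfixturevalue(which)
        idx, direction = (0, -1) if expected == "fold" else (1, 1)
        eq = S.settle_to_equilibrium(sys, (0.3, 0.2))
        branch = S.continue_branch(sys, eq, idx, direction)
        rec = S.detect_bifurcation(branch, sys.id)
        assert rec is not None
        assert rec.bif_type == expected
        assert abs(rec.mu_static) < 1e-4

    def test_classification_stable_under_halved_step(self, fold_nf, hopf_nf):
        for sys, idx, direction in ((fold_nf, 0, -1), (hopf_nf, 1, 1)):
            eq = S.settle_to_equilibrium(sys, (0.3, 0.2))
            recs = []
            for step in (0.02, 0.01):
                branch = S.continue_branch(sys, eq, idx, direction, mu_step=step)
                recs.append(S.detect_bifurcation(branch, sys.id))
            assert recs[0].bif_type == recs[1].bif_type
            assert recs[0].mu_static == pytest.approx(recs[1].mu_static, abs=1e-6)

    def test_no_crossing_returns_none(self):
        sys = make_system({1: -1.0}, {2: -1.0})
        eq = S.settle_to_equilibrium(sys, (0.4, 0.4))
        branch = S.continue_branch(sys, eq, 1, -1, mu_step=0.05, mu_span=1.0)
        assert S.detect_bifurcation(branch) is None
        assert S.detect_bifurcation(branch[:1]) is None

    def test_lambda_changes_sign_across_detected_crossing(self, small_library):
        # independent re-continuation of each record's branch: the recovery
        # rate must flip sign across consecutive re-solved equilibria and the
        # refined mu_static must sit inside (or at) that bracket
        from tipcast.simulate import record_start_state
        for system, rec in small_library:
            x0, y0 = record_start_state(system, rec)
            eq = S.settle_to_equilibrium(system, (x0, y0))
            assert eq is not None
            branch = S.continue_branch(system, eq, rec.varied_index,
                                       rec.direction, mu_step=0.01)
            lams = np.array([p.lam for p in branch])
            mus = np.array([p.mu for p in branch])
            cross = np.nonzero((lams[:-1] < 0) & (lams[1:] >= 0))[0]
            assert cross.size > 0
            i = cross[0]
            assert lams[i] < 0 <= lams[i + 1]
            span = abs(mus[-1] - mus[0])
            gap = min(abs(rec.mu_static - mus[i]), abs(rec.mu_static - mus[i + 1]))
            assert gap <= 0.05 * span + 0.02


class TestBuildLibrary:
    def test_empty_quota_gives_empty_library(self):
        assert S.build_library(0, 0, 0, rng_seed=1) == []

    def test_quota_counts_met_exactly(self, small_library):
        counts = {"fold": 0, "hopf": 0, "transcritical": 0}
        for _, rec in small_library:
            counts[rec.bif_type] += 1
        assert counts == {"fold": 3, "hopf": 3, "transcritical": 3}

    def test_jsonl_round_trip(self, small_library, tmp_path):
        path = tmp_path / "lib.jsonl"
        S.library_to_jsonl(small_library, path)
        back = S.library_from_jsonl(path)
        assert len(back) == len(small_library)
        for (s0, r0), (s1, r1) in zip(small_library, back):
            assert np.array_equal(s0.coeffs, s1.coeffs)
            assert (r0.bif_type, r0.varied_index, r0.direction) == \
                (r1.bif_type, r1.varied_index, r1.direction)
            assert r0.mu_static == pytest.approx(r1.mu_static, rel=1e-12)
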