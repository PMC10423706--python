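"""Moment formulas of the two-type branching process."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcruq.moments import (
    EfficiencyParams,
    InputCase,
    InputDistribution,
    MomentTrajectory,
    alpha_beta,
    asymptotic_cv2,
    conventional_moments,
    cross_cov,
    expected_counts,
    initial_moments,
    mean_matrix,
    moment_trajectory,
    ratio_limit,
    spectral,
    variance_counts,
)

from conftest import variance_recursion

efficiencies = st.tuples(
    st.floats(0.05, 0.99), st.floats(0.6, 1.6)
).filter(lambda t: 0 < t[0] / t[1] <= 1 and 0 < t[0] * t[1] <= 1)


class TestValidation:
    def test_p_bar_bounds(self):
        with pytest.raises(ValueError):
            EfficiencyParams(p_bar=0.0)
        with pytest.raises(ValueError):
            EfficiencyParams(p_bar=1.2)
        EfficiencyParams(p_bar=1.0)  # closed right endpoint accepted

    def test_derived_probabilities_must_be_valid(self):
        # p_rf = p_bar * R would exceed 1
        with pytest.raises(ValueError, match="p_rf"):
            EfficiencyParams(p_bar=0.95, R=1.1)

    def test_rna_case_requires_r(self):
        inp = InputDistribution(case="RF", mean_I=10.0)
        with pytest.raises(ValueError, match="r is required"):
            initial_moments(inp, EfficiencyParams(p_bar=0.9))

    def test_negative_input_mean_rejected(self):
        with pytest.raises(ValueError):
            InputDistribution(case="D", mean_I=-1.0)

    def test_family_variance_consistency(self):
        with pytest.raises(ValueError):
            InputDistribution(case="D", mean_I=5.0, family="poisson", chi=2.0)
        with pytest.raises(ValueError):
            InputDistribution(case="D", mean_I=5.0, family="negative_binomial", chi=0.9)
        fixed = InputDistribution(case="D", mean_I=5.0, family="fixed")
        assert fixed.variance == 0.0


class TestSpectral:
    @given(efficiencies)
    @settings(max_examples=300, derandomize=True)
    def test_reconstruction_and_biorthogonality(self, params):
        p_bar, R = params
        eff = EfficiencyParams(p_bar=p_bar, R=R)
        sd = spectral(eff)
        assert np.allclose(sd.matrix(), mean_matrix(eff), atol=1e-12)
        for i, x in enumerate(sd.right_vectors):
            for j, z in enumerate(sd.left_vectors):
                assert x @ z == pytest.approx(1.0 if i == j else 0.0, abs=1e-12)
        # eigenvector property A x_j = lambda_j x_j
        A = mean_matrix(eff)
        assert np.allclose(A @ sd.x1, sd.lambda1 * sd.x1, atol=1e-12)
        assert np.allclose(A @ sd.x2, sd.lambda2 * sd.x2, atol=1e-12)

    def test_unit_norms_at_symmetric_efficiencies(self):
        sd = spectral(EfficiencyParams(p_bar=0.85, R=1.0))
        for v in (*sd.right_vectors, *sd.left_vectors):
            assert np.linalg.norm(v) == pytest.approx(1.0, rel=1e-14)

    def test_eigenvalue_identities(self):
        eff = EfficiencyParams(p_bar=0.73)
        assert eff.lambda1 + eff.lambda2 == pytest.approx(2.0)
        assert eff.lambda1 * eff.lambda2 == pytest.approx(1 - eff.p_bar**2)


class TestInitialMoments:
    @pytest.mark.parametrize(
        "case,mean_I,chi_or_var,r,exp_mean,exp_var_diag",
        [
            ("D", 5.0, ("chi", 1.0), None, (5, 5), (5, 5)),
            ("RF", 10.0, ("chi", 1.0), 0.5, (0, 5), (0, 5.0)),
            ("RR", 7.0, ("var", 0.0), 1.0, (7, 0), (0, 0)),
        ],
    )
    def test_case_formulas(self, case, mean_I, chi_or_var, r, exp_mean, exp_var_diag):
        kind, value = chi_or_var
        kwargs = {"chi": value} if kind == "chi" else {"var_I": value, "family": "fixed"}
        if kind == "var":
            kwargs.pop("chi", None)
        inp = InputDistribution(case=case, mean_I=mean_I, **kwargs)
        eff = EfficiencyParams(p_bar=0.9, r=r)
        mean, var = initial_moments(inp, eff)
        assert mean == pytest.approx(exp_mean)
        assert np.diag(var) == pytest.approx(exp_var_diag)
        assert var[0, 1] == var[1, 0] == 0.0


class TestExpectedCounts:
    def test_matches_matrix_power_oracle(self, rng):
        for _ in range(25):
            p_bar = rng.uniform(0.5, 0.99)
            R = rng.uniform(max(0.8, p_bar), min(1.05, 1.0 / p_bar))
            eff = EfficiencyParams(p_bar=p_bar, R=R)
            mean0 = rng.uniform(0, 50, 2)
            traj = expected_counts(eff, mean0, 12)
            A = mean_matrix(eff)
            for i in range(13):
                oracle = np.linalg.matrix_power(A, i) @ mean0
                assert traj[i] == pytest.approx(oracle, rel=1e-11)

    def test_symmetric_two_cycle_example(self):
        eff = EfficiencyParams(p_bar=0.9, R=1.0)
        traj = expected_counts(eff, [5.0, 5.0], 2)
        assert traj[2] == pytest.approx([18.05, 18.05])
        assert traj[2].sum() == pytest.approx(10 * 1.9**2)

    def test_zero_cycles_identity(self):
        eff = EfficiencyParams(p_bar=0.8, R=1.1)
        assert expected_counts(eff, [3.0, 4.0], 0)[0] == pytest.approx([3.0, 4.0])

    def test_total_matches_conventional_growth(self):
        # summed two-type means equal E[N_0](1+p)^i at R = 1
        eff = EfficiencyParams(p_bar=0.87)
        traj = expected_counts(eff, [6.0, 6.0], 10)
        expected = 12.0 * 1.87 ** np.arange(11)
        assert traj.sum(axis=1) == pytest.approx(expected, rel=1e-12)

    def test_monotone_growth(self):
        eff = EfficiencyParams(p_bar=0.8, R=1.05)
        totals = expected_counts(eff, [0.0, 5.0], 20).sum(axis=1)
        assert np.all(np.diff(totals) > 0)

    @given(efficiencies, st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=100, derandomize=True)
    def test_weighted_sum_difference_dynamics(self, params, x0, y0):
        p_bar, R = params
        eff = EfficiencyParams(p_bar=p_bar, R=R)
        traj = expected_counts(eff, [x0, y0], 15)
        i = np.arange(16)
        ws = traj[:, 0] + R * traj[:, 1]
        wd = traj[:, 0] - R * traj[:, 1]
        scale = max(abs(x0) + R * abs(y0), 1.0)
        assert ws == pytest.approx((x0 + R * y0) * eff.lambda1**i, abs=1e-8 * scale)
        assert wd == pytest.approx(
            (x0 - R * y0) * eff.lambda2**i, abs=1e-8 * scale
        )


class TestRatioLimit:
    def test_returns_critical_ratio(self):
        assert ratio_limit(EfficiencyParams(p_bar=0.9, R=1.05)) == 1.05

    def test_rna_input_converges_to_R(self):
        eff = EfficiencyParams(p_bar=0.9, R=1.05, r=0.5)
        inp = InputDistribution(case="RF", mean_I=10.0)
        mean0, _ = initial_moments(inp, eff)
        traj = expected_counts(eff, mean0, 25)
        assert traj[25, 0] / traj[25, 1] == pytest.approx(1.05, abs=1e-6)

    def test_dna_input_ratio_relaxes_from_unity(self):
        # strongly asymmetric efficiencies: p_rf = 0.9, p_fr = 0.225
        eff = EfficiencyParams(p_bar=0.45, R=2.0)
        traj = expected_counts(eff, [5.0, 5.0], 40)
        ratios = traj[:, 0] / traj[:, 1]
        assert ratios[0] == pytest.approx(1.0)
        assert ratios[40] == pytest.approx(eff.R, abs=1e-8)


class TestVarianceCounts:
    def test_one_cycle_binomial_variance(self):
        eff = EfficiencyParams(p_bar=0.9, R=1.0)
        var = variance_counts(eff, [5.0, 5.0], np.zeros((2, 2)), 1)
        assert var[1].sum() == pytest.approx(10 * 0.9 * 0.1, rel=1e-12)

    def test_zero_cycles_identity(self):
        eff = EfficiencyParams(p_bar=0.8, R=1.02)
        var0 = np.diag([3.0, 4.0])
        assert variance_counts(eff, [5.0, 6.0], var0, 0)[0] == pytest.approx(var0)

    def test_closed_form_equals_recursion(self, rng):
        for _ in range(30):
            p_bar = rng.uniform(0.5, 0.99)
            R = rng.uniform(max(0.9, p_bar), min(1.01, 1.0 / p_bar))
            eff = EfficiencyParams(p_bar=p_bar, R=R)
            mean0 = rng.uniform(0, 30, 2)
            d = rng.uniform(0, 10, 2)
            var0 = np.diag(d)
            closed = variance_counts(eff, mean0, var0, 30)
            iterated = variance_recursion(eff, mean0, var0, 30)
            scale = np.maximum(
                np.abs(iterated).max(axis=(1, 2), keepdims=True), 1.0
            )
            assert np.max(np.abs(closed - iterated) / scale) < 1e-9

    def test_reduces_to_single_type_form(self):
        # summed entries at R = 1 equal the conventional closed form
        eff = EfficiencyParams(p_bar=0.9)
        var = variance_counts(eff, [5.0, 5.0], np.zeros((2, 2)), 20)
        _, conv = conventional_moments(0.9, 10.0, 0.0, 20)
        assert var.sum(axis=(1, 2)) == pytest.approx(conv, rel=1e-10)

    def test_perfect_efficiency_doubles_deterministically(self):
        eff = EfficiencyParams(p_bar=1.0)
        var0 = np.diag([2.0, 2.0])
        var = variance_counts(eff, [4.0, 4.0], var0, 5)
        # no reproduction noise: Var[N_i] = Var[N_0] * 4**i
        assert var.sum(axis=(1, 2)) == pytest.approx(4.0 * 4.0 ** np.arange(6))

    def test_directional_asymmetry_term_vanishes_at_R_one(self):
        # the variance surplus attributable to R != 1 shrinks quadratically
        eff1 = EfficiencyParams(p_bar=0.9, R=1.0)
        base = variance_counts(eff1, [5.0, 5.0], np.zeros((2, 2)), 15)[15].sum()
        gaps = []
        for dR in (0.04, 0.02):
            eff = EfficiencyParams(p_bar=0.9, R=1.0 + dR)
            v = variance_counts(eff, [5.0, 5.0], np.zeros((2, 2)), 15)[15].sum()
            gaps.append(abs(v - base))
        assert gaps[1] < gaps[0]


class TestCrossCovariance:
    def test_self_covariance_at_cycle_zero(self):
        eff = EfficiencyParams(p_bar=0.9)
        assert cross_cov(eff, 5.0, 3)[0] == pytest.approx(5.0)

    def test_zero_initial_variance(self):
        eff = EfficiencyParams(p_bar=0.9)
        assert np.all(cross_cov(eff, 0.0, 10) == 0)

    def test_closed_form_value(self):
        eff = EfficiencyParams(p_bar=0.9)
        assert cross_cov(eff, 5.0, 3)[3] == pytest.approx(2.5 * (1.9**3 + 0.1**3))


class TestConventionalMoments:
    def test_perfect_doubling(self):
        mean, var = conventional_moments(1.0, 3.0, 2.0, 6)
        assert mean == pytest.approx(3.0 * 2.0 ** np.arange(7))
        assert var == pytest.approx(2.0 * 4.0 ** np.arange(7))

    def test_one_step_total_variance(self):
        mean, var = conventional_moments(0.9, 10.0, 0.0, 1)
        assert mean[1] == pytest.approx(19.0)
        assert var[1] == pytest.approx(0.9)

    def test_two_type_match_at_symmetric_efficiencies(self):
        eff = EfficiencyParams(p_bar=0.92)
        inp = InputDistribution(case="D", mean_I=8.0)
        traj = moment_trajectory(eff, inp, 30)
        mean, var = conventional_moments(0.92, 16.0, 16.0, 30)
        assert traj.total_mean == pytest.approx(mean, rel=1e-10)
        assert traj.total_var == pytest.approx(var, rel=1e-10)


class TestAsymptoticCV:
    def test_alpha_beta_symmetric_dna(self):
        a, b = alpha_beta(EfficiencyParams(p_bar=0.9, R=1.0), "D")
        assert a == pytest.approx(0.5)
        assert b == pytest.approx((0.1 / 1.9) / 2)

    def test_alpha_is_unity_for_rna(self):
        for case in ("RF", "RR"):
            for R in (0.95, 1.0, 1.08):
                a, _ = alpha_beta(EfficiencyParams(p_bar=0.85, R=R, r=0.5), case)
                assert a == 1.0

    def test_asymptote_value_and_agreement_with_exact_moments(self):
        eff = EfficiencyParams(p_bar=0.9, R=1.0)
        inp = InputDistribution(case="D", mean_I=100.0)
        asym = asymptotic_cv2(eff, inp)
        assert asym == pytest.approx(0.5 / 100 + 0.0263158 / 100, rel=1e-4)
        traj = moment_trajectory(eff, inp, 40)
        exact = traj.var_U[40] / np.outer(traj.mean_U[40], traj.mean_U[40])
        assert np.max(np.abs(exact - asym) / asym) < 1e-4

    def test_perfect_amplification_leaves_only_input_noise(self):
        eff = EfficiencyParams(p_bar=1.0, R=1.0)
        inp = InputDistribution(case="D", mean_I=50.0)
        assert asymptotic_cv2(eff, inp) == pytest.approx(1.0 / (2 * 50.0))

    def test_geometric_convergence_of_exact_cv(self, rng):
        eff = EfficiencyParams(p_bar=0.9, R=1.0)
        inp = InputDistribution(case="D", mean_I=40.0)
        asym = asymptotic_cv2(eff, inp)
        traj = moment_trajectory(eff, inp, 25)
        cv2 = traj.var_U[:, 0, 0] / traj.mean_U[:, 0] ** 2
        diffs = np.abs(cv2[10:] - asym)
        assert np.all(diffs[1:] < diffs[:-1])

    def test_undefined_for_zero_input(self):
        eff = EfficiencyParams(p_bar=0.9)
        with pytest.raises(ValueError):
            asymptotic_cv2(eff, InputDistribution(case="D", mean_I=0.0))


class TestTrajectoryContainer:
    def test_roundtrip_through_frame(self):
        eff = EfficiencyParams(p_bar=0.88, R=1.02)
        inp = InputDistribution(case="D", mean_I=12.0)
        traj = moment_trajectory(eff, inp, 15)
        back = MomentTrajectory.from_frame(traj.to_frame())
        assert np.allclose(back.mean_U, traj.mean_U)
        assert np.allclose(back.var_U, traj.var_U)
        assert np.allclose(back.cov_X_X0, traj.cov_X_X0)

    def test_variance_matrices_are_symmetric_psd_diagonal(self):
        eff = EfficiencyParams(p_bar=0.8, R=1.1, r=0.4)
        inp = InputDistribution(case="RF", mean_I=30.0)
        traj = moment_trajectory(eff, inp, 25)
        assert np.allclose(traj.var_U, np.swapaxes(traj.var_U, 1, 2))
        assert np.all(traj.var_U[:, [0, 1], [0, 1]] >= 0)
        assert np.all(np.diff(traj.mean_U, axis=0) >= -1e-12)

    def test_overflow_guard(self):
        eff = EfficiencyParams(p_bar=0.9)
        with pytest.raises(ValueError, match="overflow"):
            expected_counts(eff, [1.0, 1.0], 501)
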