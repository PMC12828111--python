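"""Outcome-model evaluations, likelihood and prior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

import dosesched as ds
from dosesched.models import (
    EfficacyParams,
    ImmuneParams,
    PatientOutcome,
    ToxicityParams,
    alt2_efficacy_probs,
    efficacy_category_probs,
    efficacy_dynamic_prior_mean,
    log_likelihood_patient,
    log_prior,
    mean_immune_response,
    standardize_doses,
    toxicity_probability,
)


class TestStandardizeDoses:
    def test_reference_grid(self):
        g = standardize_doses((0.1, 0.5, 0.9))
        assert np.allclose(g.scaled_doses, (0.15309, 0.76546, 1.37783), atol=1e-5)

    def test_two_point_grid(self):
        # population SD of {1, 2} is already 0.5, so the scaling factor is 1
        g = standardize_doses((1.0, 2.0), ("a", "b"))
        assert g.scaled_doses == pytest.approx((1.0, 2.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 50.0), min_size=2, max_size=8, unique=True))
    def test_scaled_sd_is_half(self, doses):
        g = standardize_doses(sorted(doses), tuple("s" for _ in range(3)))
        assert np.std(g.scaled_doses) == pytest.approx(0.5, abs=1e-9)

    def test_constant_doses_rejected(self):
        with pytest.raises(ValueError):
            standardize_doses((1.0, 1.0), ("s1",))


def _imm(alpha=(10.0, 10.0), delta=0.4, nu=2.0, s2=1.0):
    return ImmuneParams(np.asarray(alpha, dtype=float), delta, nu, s2)


class TestImmuneResponse:
    def test_zero_at_dose_zero(self):
        g = ds.DoseGrid((0.0, 1.0), (0.0, 1.0), ("s1",))
        assert mean_immune_response(_imm(alpha=(10.0,)), g, 0, 0, 0) == 0.0

    def test_matches_published_plateau_value(self):
        # alpha=10, raw dose 0.5 with nu*d = 2.23 gives 8.93 (prints as 8.9)
        g = standardize_doses((0.1, 0.5, 0.9))
        nu = 4.46 * 0.5 / g.scaled_doses[1]  # nu on the standardized scale
        val = mean_immune_response(_imm(nu=nu), g, 1, 0, 0)
        assert val == pytest.approx(8.925, abs=0.005)

    def test_subgroup_ratio_is_exp_delta(self, grid):
        p = _imm(alpha=(10.0, 12.0, 14.0), delta=0.37)
        for j in range(3):
            for k in range(3):
                r = mean_immune_response(p, grid, j, k, 1) / mean_immune_response(
                    p, grid, j, k, 0
                )
                assert r == pytest.approx(math.exp(0.37), rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        nu=st.floats(0.1, 8.0),
        alpha=st.floats(0.5, 40.0),
        delta=st.floats(0.01, 1.5),
        m=st.integers(0, 1),
    )
    def test_increasing_in_dose_and_bounded(self, grid, nu, alpha, delta, m):
        p = _imm(alpha=(alpha,) * 3, delta=delta, nu=nu)
        vals = [mean_immune_response(p, grid, j, 0, m) for j in range(3)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] < alpha * math.exp(delta * m)


class TestToxicity:
    def test_intercept_only_baseline(self, grid):
        t = ToxicityParams(np.full(3, -4.0), 0.0)
        assert toxicity_probability(t, grid, 0, 0) == pytest.approx(0.018, abs=5e-4)

    def test_flat_slope_constant_across_doses(self, grid):
        t = ToxicityParams(np.array([-1.0, 0.0, 1.0]), 0.0)
        for k in range(3):
            ps = {toxicity_probability(t, grid, j, k) for j in range(3)}
            assert len(ps) == 1
        assert toxicity_probability(ToxicityParams(np.zeros(3), 0.0), grid, 0, 0) == 0.5


class TestEfficacyProbs:
    def test_small_lambda_limit(self):
        e = EfficacyParams(np.zeros((1, 1, 2)), 1.0, 1e-9)
        e.zeta[0, 0, 1] = 0.0
        q = efficacy_category_probs(e, 0, 0, 0)
        assert q[0] == pytest.approx(0.5, abs=1e-9)
        assert q[1] == pytest.approx(0.0, abs=1e-9)
        assert q[2] == pytest.approx(0.5, abs=1e-9)

    def test_lambda_prior_support_upper(self):
        # with the maximum shift, Pr(Y>0) reaches 0.99 when Pr(Y=2)=0.03
        zeta = np.full((1, 1, 2), logit(0.03))
        zeta[0, 0, 1] += 0.1
        e = EfficacyParams(zeta, 1.0, 7.999)
        q = efficacy_category_probs(e, 0, 0, 0)
        assert q[1] + q[2] == pytest.approx(0.99, abs=0.005)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(zeta=st.floats(-8, 8), lam=st.floats(1e-6, 7.999))
    def test_simplex_for_all_valid_params(self, zeta, lam):
        z = np.full((1, 1, 2), zeta)
        z[0, 0, 1] += 0.5
        e = EfficacyParams(z, 1.0, lam)
        q = efficacy_category_probs(e, 0, 0, 0)
        assert min(q) >= 0.0
        assert sum(q) == pytest.approx(1.0, abs=1e-12)


class TestDynamicPriorMean:
    def test_zero_gamma_is_random_walk(self, grid):
        out = efficacy_dynamic_prior_mean("proposed", -1.5, _imm(), grid, 0.0, 1, 0)
        assert out == -1.5

    def test_plateau_gives_no_drift(self, grid):
        # enormous nu: both doses saturated, so the immune increment vanishes
        out = efficacy_dynamic_prior_mean(
            "proposed", -1.5, _imm(nu=500.0), grid, 2.0, 2, 0
        )
        assert out == pytest.approx(-1.5, abs=1e-9)

    def test_unscaled_increment_value(self, grid):
        # alpha=10 with nu*d moving from 0.446 to 2.23: increment 5.33
        nu = 4.46 * 0.5 / grid.scaled_doses[1]
        out = efficacy_dynamic_prior_mean(
            "proposed", 0.0, _imm(nu=nu), grid, 1.0, 1, 0, mu_scale=1.0
        )
        assert out == pytest.approx(5.327, abs=0.005)

    def test_alternative1_uses_dose_difference(self, grid):
        out = efficacy_dynamic_prior_mean("alternative1", 0.2, _imm(), grid, 2.0, 1, 0)
        expected = 0.2 + 2.0 * (grid.scaled_doses[1] - grid.scaled_doses[0])
        assert out == pytest.approx(expected)

    def test_lowest_dose_rejected(self, grid):
        with pytest.raises(ValueError):
            efficacy_dynamic_prior_mean("proposed", 0.0, _imm(), grid, 1.0, 0, 0)


def _theta(grid):
    zeta = np.zeros((3, 3, 2))
    zeta[:, :, 1] = 0.5
    return ds.ParameterState(
        immune=_imm(alpha=(10.0, 10.0, 10.0)),
        tox=ToxicityParams(np.full(3, -1.0), 0.5),
        eff=EfficacyParams(zeta, 1.0, 2.0),
    )


class TestLikelihood:
    def test_factorizes_into_three_terms(self, grid):
        th = _theta(grid)
        o = PatientOutcome(1, 2, 1, 5.0, 1, 2)
        mu = mean_immune_response(th.immune, grid, 1, 2, 1)
        z_term = -0.5 * math.log(2 * math.pi) - (5.0 - mu) ** 2 / 2.0
        q = efficacy_category_probs(th.eff, 1, 2, 1)
        p = toxicity_probability(th.tox, grid, 1, 2)
        expected = z_term + math.log(q[2]) + math.log(p)
        assert log_likelihood_patient(th, grid, o) == pytest.approx(expected, rel=1e-12)

    def test_uniform_categories_give_log_third(self, grid):
        th = _theta(grid)
        # choose zeta/lambda so q = (1/3, 1/3, 1/3)
        th.eff.zeta[:, :, :] = logit(1.0 / 3.0)
        th.eff.lam = logit(2.0 / 3.0) - logit(1.0 / 3.0)
        mu = mean_immune_response(th.immune, grid, 0, 0, 0)
        for y in (0, 1, 2):
            o = PatientOutcome(0, 0, 0, mu, 0, y)
            ll = log_likelihood_patient(th, grid, o)
            base = (
                -0.5 * math.log(2 * math.pi)
                + math.log(1 - toxicity_probability(th.tox, grid, 0, 0))
            )
            assert ll - base == pytest.approx(math.log(1.0 / 3.0), abs=1e-9)


class TestLogPrior:
    def test_elicited_gamma_moments(self, prior):
        """The derived Gamma parameterizations reproduce the elicited mean and
        inflation-times-mean SD."""
        mean = prior.alpha_shape / prior.alpha_rate[0]
        sd = math.sqrt(prior.alpha_shape) / prior.alpha_rate[0]
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(60.0)
        d_mean = prior.delta_shape / prior.delta_rate
        assert d_mean == pytest.approx(math.log(1.5), abs=1e-12)

    def test_strict_subgroup_truncation(self, grid, hyper, prior):
        th = _theta(grid)
        th.eff.zeta[1, 1, 1] = th.eff.zeta[1, 1, 0]
        assert log_prior(th, hyper, prior, grid) == -math.inf

    def test_support_violations_give_neg_inf(self, grid, hyper, prior):
        for mutate in (
            lambda t: setattr(t.immune, "delta", -0.1),
            lambda t: setattr(t.immune, "nu", 0.0),
            lambda t: setattr(t.eff, "gamma", -1.0),
            lambda t: setattr(t.eff, "lam", 9.0),
        ):
            th = _theta(grid)
            mutate(th)
            assert log_prior(th, hyper, prior, grid) == -math.inf

    def test_finite_and_decomposable_for_interior_point(self, grid, hyper, prior):
        th = _theta(grid)
        lp = log_prior(th, hyper, prior, grid)
        assert math.isfinite(lp)
        # doubling tau^2 changes only the lowest-dose anchor terms
        hyper2 = ds.ModelHyper(zeta0=hyper.zeta0, tau_sq=2.0)
        lp2 = log_prior(th, hyper2, prior, grid)
        delta_expected = sum(
            -0.5 * math.log(2.0) - (th.eff.zeta[0, k, 0] + 2.2) ** 2 * (1 / 4.0 - 1 / 2.0)
            for k in range(3)
        )
        assert lp2 - lp == pytest.approx(delta_expected, abs=1e-9)


class TestAlt2Probs:
    def test_zero_slopes_reduce_to_intercepts(self):
        q = alt2_efficacy_probs((0.0, 30.0), 0.0, 0.0, 5.0)
        assert q[0] == pytest.approx(0.5)
        assert q[1] == pytest.approx(0.5, abs=1e-9)
        assert q[2] == pytest.approx(0.0, abs=1e-9)

    def test_subgroup_intercept_shift_improves_efficacy(self):
        # lower intercepts (M=1 under the order constraint) shift mass upward
        q0m0 = alt2_efficacy_probs((0.5, 2.0), 0.3, 0.0, 4.0)
        q0m1 = alt2_efficacy_probs((-0.5, 1.0), 0.3, 0.0, 4.0)
        assert q0m1[0] < q0m0[0]
        assert q0m1[2] > q0m0[2]

    def test_cumulative_probs_decrease_in_immune_response(self):
        lo = alt2_efficacy_probs((0.0, 1.0), -1.0, 0.0, 1.0)
        hi = alt2_efficacy_probs((0.0, 1.0), -1.0, 0.0, 3.0)
        assert hi[0] < lo[0]
        assert hi[0] + hi[1] < lo[0] + lo[1]

    def test_unordered_intercepts_rejected(self):
        with pytest.raises(ValueError):
            alt2_efficacy_probs((1.0, 0.0), 0.0, 0.0, 1.0)
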