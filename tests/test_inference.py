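"""Posterior sampling, summaries, stage-I posterior and diagnostics."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import beta as beta_dist, gamma as gamma_dist

import dosesched as ds
from dosesched.inference import (
    McmcConfig,
    PosteriorSample,
    TrialData,
    beta_binomial_safety_prob,
    gibbs_sample,
    mcmc_diagnostics,
    posterior_summaries,
    sample_prior,
)
from dosesched.models import PatientOutcome


class TestBetaBinomial:
    def test_vacuous_limit_is_certainty(self):
        assert beta_binomial_safety_prob(0, 0, 1.0) == pytest.approx(1.0)

    def test_no_toxicity_passes_screen(self):
        # Beta(0.1, 3.2) posterior after 0/3 DLTs
        val = beta_binomial_safety_prob(0, 3, 0.3)
        assert val == pytest.approx(beta_dist.cdf(0.3, 0.1, 3.2), abs=1e-12)
        assert val > 0.95

    def test_all_toxic_fails_screen(self):
        # Beta(3.1, 0.2) posterior after 3/3 DLTs fails the C_I = 0.05 screen
        val = beta_binomial_safety_prob(3, 3, 0.3)
        assert val == pytest.approx(beta_dist.cdf(0.3, 3.1, 0.2), abs=1e-12)
        assert val < 0.05

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_safety_prob(4, 3, 0.3)


class TestGibbsSampler:
    def test_empty_data_rejected(self, grid, hyper, prior, quick_mcmc):
        with pytest.raises(ValueError, match="no patient data"):
            gibbs_sample(TrialData(), grid, hyper, prior, quick_mcmc())

    def test_zero_length_chain_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_burn=100, n_keep=0)

    def test_same_seed_identical_draws(self, grid, hyper, prior, quick_mcmc, model_data_factory):
        data, _ = model_data_factory(3, n_per_cell=4)
        a = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=5))
        b = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=5))
        for key in a.draws:
            assert np.array_equal(a.draws[key], b.draws[key])
        c = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=6))
        assert not np.array_equal(a.draws["nu"], c.draws["nu"])

    def test_posterior_recovers_simulation_truth(self, grid, hyper, prior, model_data_factory):
        """Posterior means on a large balanced dataset land within 3 posterior
        SDs of the generating values for the global parameters."""
        data, theta = model_data_factory(11, n_per_cell=66)
        post = gibbs_sample(data, grid, hyper, prior, McmcConfig(1000, 2000, seed=1))
        for name, true in (
            ("nu", theta.immune.nu),
            ("delta", theta.immune.delta),
            ("lam", theta.eff.lam),
            ("sigma_z_sq", theta.immune.sigma_z_sq),
        ):
            dr = post.draws[name]
            assert abs(dr.mean() - true) < 3.0 * dr.std() + 1e-6, name

    def test_all_draws_satisfy_hard_constraints(self, grid, hyper, prior, quick_mcmc, model_data_factory):
        data, _ = model_data_factory(7, n_per_cell=3)
        post = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=2))
        d = post.draws
        assert (d["alpha"] > 0).all()
        assert (d["delta"] > 0).all()
        assert (d["nu"] > 0).all()
        assert (d["gamma"] > 0).all()
        assert (d["sigma_z_sq"] > 0).all()
        assert ((d["lam"] > 0) & (d["lam"] < 8.0)).all()
        assert (d["zeta"][:, :, :, 1] > d["zeta"][:, :, :, 0]).all()

    def test_alternative1_ignores_immune_response(self, grid, hyper, prior, quick_mcmc, model_data_factory):
        data, _ = model_data_factory(13, n_per_cell=4)
        shuffled = TrialData(
            [
                PatientOutcome(o.j, o.k, o.m, z, o.x, o.y)
                for o, z in zip(
                    data.records, [r.z * 100.0 for r in reversed(data.records)]
                )
            ]
        )
        a = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=4), "alternative1")
        b = gibbs_sample(shuffled, grid, hyper, prior, quick_mcmc(seed=4), "alternative1")
        assert np.array_equal(a.q2_draws, b.q2_draws)
        assert np.array_equal(a.p_draws, b.p_draws)

    @pytest.mark.parametrize("variant", ["dose_adjusted", "alternative2"])
    def test_variants_produce_valid_probability_draws(
        self, variant, grid, hyper, prior, quick_mcmc, model_data_factory
    ):
        data, _ = model_data_factory(17, n_per_cell=4)
        post = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=8), variant)
        q0 = 1.0 - post.q1_draws - post.q2_draws
        for arr in (post.q1_draws, post.q2_draws, q0, post.p_draws):
            assert (arr >= -1e-12).all() and (arr <= 1.0 + 1e-12).all()


class TestPriorOnlySampling:
    def test_prior_marginals_match_analytic_forms(self, grid, hyper, prior):
        s = sample_prior(grid, hyper, prior, McmcConfig(500, 6000, seed=42))
        a = s.draws["alpha"][:, 0]
        want = gamma_dist.ppf([0.25, 0.5, 0.75], prior.alpha_shape,
                              scale=1.0 / prior.alpha_rate[0])
        got = np.quantile(a, [0.25, 0.5, 0.75])
        assert np.allclose(got, want, rtol=0.2, atol=0.02)
        assert a.mean() == pytest.approx(20.0, abs=6.0)
        # no-dose toxicity probability: Pr(expit(beta0) < 0.12) ~ 0.975
        frac = (expit(s.draws["beta0"][:, 0]) < 0.12).mean()
        assert frac == pytest.approx(0.975, abs=0.02)
        # every prior draw satisfies the parameter constraints
        assert (s.draws["zeta"][:, :, :, 1] > s.draws["zeta"][:, :, :, 0]).all()
        assert (s.draws["delta"] > 0).all() and (s.draws["nu"] > 0).all()


def _degenerate_sample(p_val, q1_val, q2_val, n=50, J=3, K=3):
    p = np.full((n, J, K), p_val)
    q1 = np.full((n, J, K, 2), q1_val)
    q2 = np.full((n, J, K, 2), q2_val)
    return PosteriorSample(
        draws={}, p_draws=p, q1_draws=q1, q2_draws=q2,
        acceptance={}, config=McmcConfig(seed=0), variant="proposed",
    )


class TestPosteriorSummaries:
    def test_degenerate_safe_sample(self, grid):
        s = _degenerate_sample(0.1, 0.3, 0.2)
        sums = posterior_summaries(s, grid, phi_T=0.3, phi_E=0.3)
        assert (sums.prob_safe == 1.0).all()
        assert (sums.prob_efficacious == 1.0).all()
        assert np.allclose(sums.q1_hat + sums.q2_hat + (1 - sums.q1_hat - sums.q2_hat), 1.0)

    def test_draws_symmetric_around_cutoff(self, grid):
        s = _degenerate_sample(0.1, 0.3, 0.2)
        s.p_draws[::2] = 0.25
        s.p_draws[1::2] = 0.35
        sums = posterior_summaries(s, grid, phi_T=0.3, phi_E=0.3)
        assert np.allclose(sums.prob_safe, 0.5, atol=0.02)

    def test_posterior_mean_category_probs_sum_to_one(
        self, grid, hyper, prior, quick_mcmc, model_data_factory
    ):
        data, _ = model_data_factory(19, n_per_cell=4)
        post = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=1))
        sums = posterior_summaries(post, grid, 0.3, 0.3)
        q0_hat = (1.0 - post.q1_draws - post.q2_draws).mean(axis=0)
        assert np.allclose(q0_hat + sums.q1_hat + sums.q2_hat, 1.0, atol=1e-12)


class TestDiagnostics:
    def test_report_covers_scalars_and_flags_constant_chain(
        self, grid, hyper, prior, quick_mcmc, model_data_factory
    ):
        data, _ = model_data_factory(23, n_per_cell=4)
        post = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=3))
        rep = mcmc_diagnostics(post)
        # every scalar in the parameter state appears
        for name in ("nu", "delta", "sigma_z_sq", "beta1", "gamma", "lambda"):
            assert name in rep.ess
        assert "zeta[1,1,0]" in rep.ess
        finite = [v for v in rep.rhat.values() if np.isfinite(v)]
        assert max(finite) < 1.6  # short demo chain, loose bound
        # inject a constant column
        post.draws["nu"] = np.zeros_like(post.draws["nu"]) + 1.0
        rep2 = mcmc_diagnostics(post)
        assert any("zero-variance" in w for w in rep2.warnings)

    def test_export_round_trip(self, tmp_path, grid, hyper, prior, quick_mcmc, model_data_factory):
        data, _ = model_data_factory(29, n_per_cell=3)
        post = gibbs_sample(data, grid, hyper, prior, quick_mcmc(seed=9, n_burn=100, n_keep=50))
        out = tmp_path / "draws.csv"
        post.export_csv(out)
        import pandas as pd

        df = pd.read_csv(out)
        assert len(df) == 50
        assert "nu" in df.columns and "zeta[1,1,0]" in df.columns


class TestTrialDataCsv:
    def test_round_trip(self, tmp_path):
        data = TrialData(
            [PatientOutcome(0, 1, 1, 3.5, 0, 2), PatientOutcome(2, 0, 0, -0.5, 1, 0)]
        )
        path = tmp_path / "records.csv"
        data.to_csv(path)
        back = TrialData.from_csv(path)
        assert back.records == data.records

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("dose_index,schedule_index\n1,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            TrialData.from_csv(path)
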