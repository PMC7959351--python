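"""Beta-regression likelihood, ML fit, and constrained posterior sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from weedcover import betareg as br
from weedcover import synthetic as sy
from .conftest import random_admissible


class TestLinearPredictor:
    def test_all_zero_params(self):
        p = br.BetaRegParams(alpha0=0.0)
        for g in ("C", "P0", "P1"):
            assert br.linear_predictor(p, 3.0, g) == 0.0

    def test_control_reduces_to_intercept_plus_slope(self):
        p = br.BetaRegParams(alpha0=-1.5, alpha1=9, alpha2=9, beta0=0.4, beta1=9, beta2=9)
        assert br.linear_predictor(p, 2.0, "C") == pytest.approx(-1.5 + 0.4 * 2.0)

    def test_gray_zone_hand_arithmetic(self):
        p = br.BetaRegParams(alpha0=-2.0, alpha2=1.0, beta0=0.5, beta2=-0.3)
        assert br.linear_predictor(p, 5.0, "P1") == pytest.approx(0.0)

    def test_whole_pot_label_uses_first_dummy_slot(self):
        p = br.BetaRegParams(alpha0=-2.0, alpha1=-1.0, beta0=0.5, beta1=0.1)
        assert br.linear_predictor(p, 2.0, "T") == br.linear_predictor(p, 2.0, "P0")

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            br.linear_predictor(br.BetaRegParams(alpha0=0), 1.0, "X")

    @given(st.floats(-5, 5), st.floats(0, 10))
    def test_intercept_shift_equivariance(self, c, day):
        """Adding c to alpha0 and subtracting it from alpha1, alpha2 moves
        only the control's mean — the dummy coding is a pure relabeling."""
        base = br.BetaRegParams(-1.0, 0.5, -0.5, 0.6, -0.1, -0.2, 1.0, 0.0)
        shifted = br.BetaRegParams(
            -1.0 + c, 0.5 - c, -0.5 - c, 0.6, -0.1, -0.2, 1.0, 0.0
        )
        for g in ("P0", "P1"):
            assert br.mean_mu(shifted, day, g) == pytest.approx(
                br.mean_mu(base, day, g), rel=1e-12
            )


class TestMeanAndPrecision:
    def test_logit_inverse_values(self):
        p = br.BetaRegParams(alpha0=0.0)
        assert br.mean_mu(p, 0.0, "C") == 0.5
        p2 = br.BetaRegParams(alpha0=-2.0)
        assert br.mean_mu(p2, 0.0, "C") == pytest.approx(0.11920, abs=1e-5)

    def test_saturation_without_overflow(self):
        p = br.BetaRegParams(alpha0=800.0)
        mu = br.mean_mu(p, 0.0, "C")
        assert 0.0 < mu <= 1.0 and np.isfinite(mu)

    def test_precision_log_link(self):
        assert br.precision_phi(br.BetaRegParams(0.0), 3.0) == 1.0
        p = br.BetaRegParams(alpha0=0, gamma0=3.0, gamma1=-0.2)
        assert br.precision_phi(p, 5.0) == pytest.approx(np.exp(2.0))
        assert br.precision_phi(br.BetaRegParams(0, gamma0=-40), 0.0) > 0


class TestLogLikelihood:
    def _obs(self, y, day=1.0, group="C"):
        return pd.DataFrame(
            {"pot_id": [f"p{i}" for i in range(len(y))],
             "group": group, "day": day, "proportion": y}
        )

    def test_uniform_case_log_density_zero(self):
        # mu=0.5, phi=2 => Beta(1,1), the uniform density
        p = br.BetaRegParams(alpha0=0.0, gamma0=np.log(2.0))
        assert br.log_likelihood(p, self._obs([0.37])) == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_duplicates(self):
        p = br.BetaRegParams(alpha0=-0.5, beta0=0.2, gamma0=1.5, gamma1=0.1)
        single = br.log_likelihood(p, self._obs([0.21], day=3.0))
        kfold = br.log_likelihood(p, self._obs([0.21] * 7, day=3.0))
        assert kfold == pytest.approx(7 * single, rel=1e-12)

    def test_matches_scipy_beta_logpdf(self):
        """Independent density oracle on random instances, 1e-10."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_admissible(rng)
            days = rng.choice([0.5, 1, 2, 4, 5], size=5)
            groups = rng.choice(["C", "P0", "P1"], size=5)
            y = rng.uniform(0.02, 0.98, size=5)
            obs = pd.DataFrame(
                {"pot_id": list("abcde"), "group": groups, "day": days, "proportion": y}
            )
            mu = np.array([br.mean_mu(p, d, g) for d, g in zip(days, groups)])
            phi = np.array([br.precision_phi(p, d) for d in days])
            expect = stats.beta.logpdf(y, mu * phi, (1 - mu) * phi).sum()
            assert br.log_likelihood(p, obs) == pytest.approx(expect, abs=1e-10)

    def test_boundary_outcome_raises_with_nudge_hint(self):
        p = br.BetaRegParams(alpha0=0.0)
        with pytest.raises(br.BoundaryDataError, match="nudge"):
            br.log_likelihood(p, self._obs([0.0, 0.5]))

    def test_nudge_pulls_boundaries_interior(self):
        y = np.array([0.0, 0.5, 1.0])
        z = br.nudge_boundary(y)
        assert (z > 0).all() and (z < 1).all()
        assert z[1] == pytest.approx(0.5, abs=0.2)


@pytest.fixture(scope="module")
def recovery_data():
    """320 observations from known admissible truth: 16 design days,
    pots split 7/7/6 across the three groups."""
    truth = sy.TruthParams(
        alpha0=-3.0, alpha1=-0.3, alpha2=-0.6,
        beta0=0.5, beta1=0.1, beta2=-0.3,
        gamma0=3.5, gamma1=-0.1,
    )
    days = tuple(np.arange(0.5, 8.5, 0.5))
    tables = []
    for g, pots in (("C", 7), ("P0", 7), ("P1", 6)):
        d = sy.StudyDesign(pots_per_group=pots, days=days, groups=(g,))
        tables.append(sy.simulate_proportions(truth, d, seed=2024))
    obs = pd.concat(tables, ignore_index=True)
    assert len(obs) == 320
    return truth, obs


class TestFitML:
    def test_recovers_truth_within_three_standard_errors(self, recovery_data):
        truth, obs = recovery_data
        est, report = br.fit_ml(obs)
        assert report.converged
        t = truth
        true_vec = dict(zip(br.ALL_COEF,
                            [t.alpha0, t.alpha1, t.alpha2, t.beta0, t.beta1,
                             t.beta2, t.gamma0, t.gamma1]))
        for name in br.ALL_COEF:
            err = abs(getattr(est, name) - true_vec[name])
            assert err < 3 * report.std_errors[name], name

    def test_fitted_loglik_beats_truth(self, recovery_data):
        truth, obs = recovery_data
        est, report = br.fit_ml(obs)
        p_true = br.BetaRegParams(
            truth.alpha0, truth.alpha1, truth.alpha2,
            truth.beta0, truth.beta1, truth.beta2,
            truth.gamma0, truth.gamma1,
        )
        assert report.loglik >= br.log_likelihood(p_true, obs)

    def test_duplicating_data_leaves_estimates_unchanged(self, recovery_data):
        _, obs = recovery_data
        est1, _ = br.fit_ml(obs)
        est2, _ = br.fit_ml(pd.concat([obs, obs], ignore_index=True))
        assert np.allclose(est1.as_array(), est2.as_array(), atol=1e-3)

    def test_two_group_whole_pot_fit(self, truth, design):
        obs = sy.simulate_proportions(truth, design, seed=3)
        obs = obs[obs["group"].isin(["C", "P0"])].copy()
        obs.loc[obs["group"] == "P0", "group"] = "T"
        est, report = br.fit_ml(obs)
        assert report.converged
        assert np.isnan(est.alpha2) and np.isnan(est.beta2)
        assert np.isfinite(est.alpha1) and np.isfinite(est.beta1)

    def test_input_guards(self, truth):
        small = sy.simulate_proportions(
            truth, sy.StudyDesign(pots_per_group=1, days=(1.0, 2.0), groups=("C",)), 0
        )
        with pytest.raises(ValueError, match="at least 10"):
            br.fit_ml(small)


class TestSamplePosterior:
    def test_same_seed_identical_draws(self, obs_table):
        a = br.sample_posterior(obs_table, n_chains=2, n_iter=200, n_warmup=200, seed=4)
        b = br.sample_posterior(obs_table, n_chains=2, n_iter=200, n_warmup=200, seed=4)
        assert np.array_equal(a.draws, b.draws)

    def test_every_draw_is_admissible(self, obs_table):
        d = br.sample_posterior(obs_table, n_chains=2, n_iter=400, n_warmup=400, seed=5)
        df = d.to_frame()
        assert (df["beta0"] > 0).all()
        assert (df["beta0"] + df["beta1"] > 0).all()
        assert (df["beta0"] + df["beta2"] > 0).all()

    def test_posterior_means_approach_ml_at_large_n(self, recovery_data):
        """With flat-ish priors and n=320 the constrained posterior should
        concentrate near the (admissible) ML solution."""
        _, obs = recovery_data
        ml, report = br.fit_ml(obs)
        assert br.BetaRegParams(*ml.as_array()).is_admissible()
        d = br.sample_posterior(
            obs,
            priors=br.PriorSpec(mean_scale=10.0, precision_scale=5.0),
            n_chains=2, n_iter=1500, n_warmup=1000, seed=6,
        )
        post_mean = d.to_frame().mean()
        for name in br.ALL_COEF:
            se = report.std_errors[name]
            assert abs(post_mean[name] - getattr(ml, name)) < 1.0 * se, name

    def test_reports_convergence_diagnostics(self, obs_table):
        d = br.sample_posterior(obs_table, n_chains=2, n_iter=300, n_warmup=300, seed=8)
        assert set(d.rhat) == set(d.names)
        assert all(v > 0 for v in d.ess.values())
        assert 0.0 < d.accept_rate < 1.0
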