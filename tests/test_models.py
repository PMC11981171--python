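"""Model specification, compiled log-joint, and augmentation consistency."""

import numpy as np
import pytest
from scipy import stats

from nblcrash.distributions import lindley_sample, nb_pmf, nbl_pmf_oracle
from nblcrash.models import (
    LatentState,
    ModelSpecError,
    PriorConfig,
    init_state,
    log_joint,
    log_likelihood,
    log_mixing,
    log_prior,
    nb_mean,
    specify_model,
)
from conftest import make_panel


class TestSpecifyModel:
    def test_nb_parameter_count(self):
        spec = specify_model("NB", ("ln_SL",))
        assert spec.n_free_parameters() == 3  # slope, intercept, alpha

    def test_rpnbl_parameter_count(self):
        spec = specify_model("RPNB-L", ("a", "b", "c"), random_candidates=("a", "b", "c"))
        # 3 population means + 3 sigmas + intercept + theta + alpha
        assert spec.n_free_parameters() == 9

    def test_random_candidates_require_rpnbl(self):
        with pytest.raises(ModelSpecError):
            specify_model("NB-L", ("x",), random_candidates=("x",))

    def test_unknown_family_rejected(self):
        with pytest.raises(ModelSpecError):
            specify_model("ZIP", ("x",))

    def test_empty_covariates_rejected(self):
        with pytest.raises(ModelSpecError):
            specify_model("NB", ())


class TestLogJoint:
    def test_single_observation_nb_loglik(self):
        panel = make_panel(1, 1, y=[0], x=[0.0])
        spec = specify_model("NB", ("x",))
        state = init_state(spec, panel)
        state.alpha = 1.0  # eta = exp(0) = 1
        assert log_likelihood(spec, state, panel) == pytest.approx(np.log(0.5))

    def test_compiled_joint_equals_hand_summed_terms(self):
        """Term-by-term oracle using scipy's distributions for NB-L."""
        panel = make_panel(3, 1, y=[0, 2, 5], x=[0.1, -0.2, 0.4], seed=1)
        spec = specify_model("NB-L", ("x",))
        state = init_state(spec, panel)
        state.beta[:] = [0.7]
        state.intercept = -0.5
        state.alpha, state.theta = 0.8, 1.3
        state.tau = np.array([0.5, 1.2, 2.0])
        state.chi = np.array([0, 1, 1], dtype=np.int8)

        lam = np.exp(-0.5 + 0.7 * panel.covariate_values("x"))
        eta = state.tau * lam
        r = 1.0 / 0.8
        expected = stats.nbinom.logpmf(panel.y, r, r / (r + eta)).sum()
        expected += stats.gamma.logpdf(state.tau, a=1 + state.chi, scale=1 / 1.3).sum()
        p1 = 1 / (1 + 1.3)
        expected += stats.bernoulli.logpmf(state.chi, p1).sum()
        pri = spec.priors
        expected += stats.norm.logpdf(0.7, pri.beta_loc, np.sqrt(pri.beta_var))
        expected += stats.norm.logpdf(-0.5, pri.beta_loc, np.sqrt(pri.beta_var))
        expected += stats.gamma.logpdf(0.8, a=pri.alpha_shape, scale=1 / pri.alpha_rate)
        expected += stats.gamma.logpdf(1.3, a=pri.theta_shape, scale=1 / pri.theta_rate)

        assert log_joint(spec, state, panel) == pytest.approx(expected, abs=1e-10)

    def test_likelihood_invariant_to_observation_order(self):
        panel = make_panel(10, 2, seed=3)
        spec = specify_model("NB", ("x",))
        state = init_state(spec, panel)
        state.beta[:] = [0.4]
        ll = log_likelihood(spec, state, panel)
        df = panel.df.copy()
        df["segment_id"] = df["segment_id"].map(
            {i: 9 - i for i in range(10)})  # reverse segment labels
        from nblcrash.panel import CrashPanel
        permuted = CrashPanel(df, panel.schema)
        assert log_likelihood(spec, state, permuted) == pytest.approx(ll)

    def test_dimension_mismatch_rejected(self):
        panel = make_panel(4, 2, seed=0)
        spec = specify_model("NB", ("x",))
        state = init_state(spec, panel)
        with pytest.raises(ModelSpecError):
            log_likelihood(spec, state, panel, X=np.ones((3, 1)))


class TestAugmentationConsistency:
    def test_marginalized_augmentation_matches_oracle(self):
        """Averaging the NB kernel over Lindley draws reproduces the compound pmf."""
        lam, theta, alpha = 1.4, 1.2, 0.9
        tau = lindley_sample(theta, 100_000, seed=17)
        for y in (0, 1, 4):
            vals = nb_pmf(y, (tau * lam, alpha))
            se = vals.std() / np.sqrt(vals.size)
            assert abs(vals.mean() - nbl_pmf_oracle(y, lam, theta, alpha)) < 3 * se

    def test_panel_marginal_likelihood_three_obs(self):
        """Per-cell quadrature marginal equals the product of compound pmfs."""
        panel = make_panel(3, 1, y=[0, 1, 3], x=[0.0, 0.5, -0.5], seed=2)
        theta, alpha, b0, b1 = 1.5, 0.8, -0.2, 0.6
        lam = np.exp(b0 + b1 * panel.covariate_values("x"))
        marginal = sum(np.log(nbl_pmf_oracle(int(y), l, theta, alpha))
                       for y, l in zip(panel.y, lam))
        # Monte-Carlo marginalization of the augmented likelihood
        rng_tau = lindley_sample(theta, 200_000, seed=23)
        mc = 0.0
        for y, l in zip(panel.y, lam):
            mc += np.log(np.mean(nb_pmf(int(y), (rng_tau * l, alpha))))
        assert mc == pytest.approx(marginal, abs=0.01)

    def test_rpnbl_zero_sigma_matches_nbl_likelihood(self):
        """With all random deviations at 0 the RPNB-L mean equals NB-L's."""
        panel = make_panel(6, 2, seed=4)
        nbl = specify_model("NB-L", ("x",))
        rp = specify_model("RPNB-L", ("x",), random_candidates=("x",))
        s1 = init_state(nbl, panel)
        s2 = init_state(rp, panel)
        for s in (s1, s2):
            s.beta[:] = [0.5]
            s.intercept = -0.3
            s.alpha, s.theta = 0.7, 1.1
            s.tau = np.linspace(0.2, 2.0, panel.n)
            s.chi = np.zeros(panel.n, dtype=np.int8)
        s2.w["x"][:] = 0.0
        X = panel.design_matrix(["x"])
        np.testing.assert_allclose(nb_mean(rp, s2, X), nb_mean(nbl, s1, X))
        assert log_likelihood(rp, s2, panel) == pytest.approx(
            log_likelihood(nbl, s1, panel))

    def test_intercept_re_degenerates_to_nbl(self):
        """A point-mass random intercept (e_it = c) reproduces NB-L's mean."""
        panel = make_panel(5, 2, seed=6)
        nbl = specify_model("NB-L", ("x",))
        ere = specify_model("RENB-L-intercept", ("x",))
        s1 = init_state(nbl, panel)
        s2 = init_state(ere, panel)
        for s in (s1, s2):
            s.beta[:] = [0.4]
            s.alpha, s.theta = 0.9, 1.4
            s.tau = np.full(panel.n, 0.8)
            s.chi = np.zeros(panel.n, dtype=np.int8)
        s1.intercept = -0.6
        s2.c = -0.6
        s2.intercept_re = np.full(panel.n, -0.6)
        X = panel.design_matrix(["x"])
        np.testing.assert_allclose(nb_mean(ere, s2, X), nb_mean(nbl, s1, X))

    def test_mixing_and_prior_are_finite_at_init(self):
        panel = make_panel(4, 2, seed=8)
        for family in ("NB", "NB-GE", "NB-L", "RENB-L-alpha",
                       "RENB-L-intercept", "RPNB-L"):
            spec = specify_model(family, ("x",),
                                 random_candidates=("x",) if family == "RPNB-L" else ())
            state = init_state(spec, panel)
            assert np.isfinite(log_mixing(spec, state))
            assert np.isfinite(log_prior(spec, state))
            assert np.isfinite(log_likelihood(spec, state, panel))


class TestPriorConfig:
    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ModelSpecError):
            PriorConfig(beta_var=-1.0)

    def test_defaults_follow_shape_rate_convention(self):
        pri = PriorConfig()
        assert (pri.theta_shape, pri.theta_rate) == (0.3, 0.5)
        assert (pri.ge_shape, pri.ge_rate) == (0.01, 0.01)
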