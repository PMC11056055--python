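"""Linear predictors, likelihoods, priors and gradients of the four models."""

import numpy as np
import pytest

from stcar import (
    MODEL_NAMES,
    PanelData,
    ParameterState,
    build_model,
    generate_panel,
    log_likelihood,
    log_posterior,
    log_prior,
    recenter_effects,
    temporal_adjacency,
)
from stcar.simulate import Scenario


def zero_state(model):
    """All effects zero, beta zero, rho = 0.5, all variances 1."""
    theta = np.zeros(model.dim)
    for name in model._var_blocks:
        theta[model._slices[name]] = 0.0  # log k2 = 0 -> k2 = 1
    return model.unpack(theta)


@pytest.fixture(scope="module")
def models(small_data):
    return {name: build_model(name, small_data) for name in MODEL_NAMES}


class TestLinearPredictor:
    def test_zero_state_reduces_to_offset(self, models, small_data):
        for name, m in models.items():
            eta = m.linear_predictor(zero_state(m))
            assert np.allclose(eta, small_data.offset), name

    def test_spltm_slope_vanishes_at_central_time(self, small_data):
        """At t = tbar = (T+1)/2 the (omega2 + b_i) term contributes nothing."""
        m = build_model("SPLTM", small_data)
        st = zero_state(m)
        st.params["omega2"] = 3.0
        st.params["b"] = np.arange(m.N, dtype=float)
        eta = m.linear_predictor(st)
        T = m.T
        # the score (t - (T+1)/2)/T changes sign symmetrically around tbar
        score = (np.arange(1, T + 1) - (T + 1) / 2) / T
        assert np.allclose(eta - small_data.offset,
                           (3.0 + st.params["b"][:, None]) * score[None, :])
        # interpolated zero at tbar: symmetric scores sum to zero
        assert score.sum() == pytest.approx(0.0)

    def test_spam_additive_arithmetic(self, small_data):
        m = build_model("SPAM", small_data)
        st = zero_state(m)
        st.params["a"] = np.full(m.N, 1.0)
        st.params["b"] = np.full(m.T, 2.0)
        st.params["c"] = np.full((m.N, m.T), 3.0)
        assert np.allclose(m.linear_predictor(st), small_data.offset + 6.0)

    def test_state_model_mismatch(self, models):
        from stcar.models import linear_predictor

        st = zero_state(models["SPAM"])
        with pytest.raises(ValueError):
            linear_predictor(models["TMS"], st)


class TestLogLikelihood:
    def test_pointwise_values(self, models):
        """Poisson log pmf: y=1, mu=1 -> -1; y=2, mu=2 -> log 2 - 2."""
        m = models["TMS"]
        st = zero_state(m)
        pw = m.pointwise_loglik(st)  # all mu = exp(offset) = 1
        y = m.data.y
        assert np.allclose(pw[y == 1], -1.0)
        st2 = zero_state(m)
        st2.params["a"] = np.full((m.N, m.T), np.log(2.0))  # mu = 2 everywhere
        pw2 = m.pointwise_loglik(st2)
        assert np.allclose(pw2[y == 2], np.log(2.0) - 2.0)

    def test_vanishing_intensity_is_minus_infinity(self, models):
        m = models["TMS"]
        st = zero_state(m)
        st.params["a"] = np.full((m.N, m.T), -800.0)  # mu underflows to 0
        total, pw = log_likelihood(st, m)
        assert total == -np.inf

    def test_total_is_masked_sum(self, small_panel):
        mask = np.zeros(small_panel.y.shape, dtype=bool)
        mask[:, :3] = True
        data = PanelData(
            y=small_panel.y, offset=small_panel.offset, X=small_panel.X,
            graph=small_panel.graph, tgraph=temporal_adjacency(small_panel.y.shape[1]),
            mask=mask,
        )
        m = build_model("SPAM", data)
        st = zero_state(m)
        total, pw = log_likelihood(st, m)
        assert total == pytest.approx(pw[mask].sum())


class TestLogPrior:
    def test_spam_interaction_at_origin(self, models):
        """c = 0 with k2_I = 1 contributes -(N T / 2) log(2 pi)."""
        m = models["SPAM"]
        st = zero_state(m)
        lp_with = log_prior(st, m)
        st2 = zero_state(m)
        st2.params["k2_I"] = 4.0
        lp_scaled = log_prior(st2, m)
        NT = m.N * m.T
        # difference isolates the interaction block's normalising constant
        # plus the IG prior difference on k2_I
        from scipy.stats import invgamma

        ig = invgamma(a=1.0, scale=0.01)
        expected = NT / 2 * np.log(4.0) + ig.logpdf(1.0) - ig.logpdf(4.0)
        assert lp_with - lp_scaled == pytest.approx(expected, rel=1e-9)

    def test_tms_zero_lag_factorizes(self, small_data):
        """With rho_T -> 0 the TMS prior is a product of identical CAR terms."""
        from stcar.graphs import CarParams, car_log_density

        m = build_model("TMS", small_data)
        st = zero_state(m)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(m.N, m.T))
        st.params["a"] = A
        st.params["rho_T"] = 1e-12
        st.params["rho_s"] = 0.4
        lp = m._effect_log_prior(st)
        car = CarParams(0.4, 1.0)
        expected = sum(
            car_log_density(A[:, t], car, m.data.graph) for t in range(m.T)
        )
        assert lp == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_variance_rejected(self, models):
        m = models["SPAM"]
        st = zero_state(m)
        st.params["k2_s"] = -1.0
        assert log_prior(st, m) == -np.inf


class TestLogPosterior:
    def test_is_likelihood_plus_prior(self, models, rng):
        for name, m in models.items():
            st = m.unpack(0.2 * rng.standard_normal(m.dim))
            ll, _ = log_likelihood(st, m)
            assert log_posterior(st, m) == pytest.approx(
                ll + log_prior(st, m), rel=1e-12
            ), name

    def test_permutation_invariance(self):
        """Relabelling units consistently leaves the posterior unchanged."""
        panel = generate_panel(Scenario(sp=0.4, tm=0.4, n_units=4, n_times=3, seed=8))
        tg = temporal_adjacency(3)
        data = PanelData(y=panel.y, offset=panel.offset, X=panel.X,
                         graph=panel.graph, tgraph=tg)
        m = build_model("SPAM", data)
        st = m.unpack(0.3 * np.random.default_rng(1).standard_normal(m.dim))
        lp0 = log_posterior(st, m)

        perm = np.array([2, 0, 3, 1])
        from stcar.graphs import SpatialGraph

        data_p = PanelData(
            y=panel.y[perm], offset=panel.offset[perm], X=panel.X[perm],
            graph=SpatialGraph(panel.graph.W[np.ix_(perm, perm)]), tgraph=tg,
        )
        m_p = build_model("SPAM", data_p)
        st_p = ParameterState("SPAM", dict(st.params))
        st_p.params["a"] = np.asarray(st.params["a"])[perm]
        st_p.params["c"] = np.asarray(st.params["c"])[perm]
        assert log_posterior(st_p, m_p) == pytest.approx(lp0, rel=1e-10)


class TestGradients:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    @pytest.mark.parametrize("centered", [True, False])
    def test_analytic_gradient_matches_finite_differences(
        self, small_data, name, centered, rng
    ):
        m = build_model(name, small_data, centered=centered)
        theta = 0.3 * rng.standard_normal(m.dim)
        _, grad = m._logp_and_grad_py(theta)
        eps = 1e-6
        idx = rng.choice(m.dim, size=min(25, m.dim), replace=False)
        for i in idx:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (m._logp_and_grad_py(tp)[0] - m._logp_and_grad_py(tm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6), (name, i)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_compiled_kernel_matches_reference(self, small_data, name, rng):
        """The fused kernel and the numpy path must agree to round-off."""
        m = build_model(name, small_data)
        assert m._kernel is not None
        for _ in range(5):
            theta = 0.5 * rng.standard_normal(m.dim)
            for lik in (True, False):
                lp_k, g_k = m._kernel(theta, *m._kernel_args, lik)
                lp_p, g_p = m._logp_and_grad_py(theta, lik)
                assert lp_k == pytest.approx(lp_p, rel=1e-10, abs=1e-8)
                assert np.allclose(g_k, g_p, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_parameterizations_target_same_posterior(self, small_data, name, rng):
        """Centered and non-centered thetas representing the same natural
        state must give the same log_posterior through unpack."""
        mc = build_model(name, small_data, centered=True)
        mn = build_model(name, small_data, centered=False)
        theta = 0.3 * rng.standard_normal(mc.dim)
        st = mc.unpack(theta)
        theta_n = mn.pack(st)
        st_back = mn.unpack(theta_n)
        assert log_posterior(st, mc) == pytest.approx(
            log_posterior(st_back, mn), rel=1e-10
        )

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_pack_unpack_roundtrip(self, small_data, name, rng):
        for centered in (True, False):
            m = build_model(name, small_data, centered=centered)
            theta = rng.standard_normal(m.dim)
            assert np.allclose(m.pack(m.unpack(theta)), theta, atol=1e-12)


class TestRecentering:
    @pytest.mark.parametrize("name", ["SPLTM", "SPAM"])
    def test_fitted_log_mu_unchanged(self, small_data, name, rng):
        m = build_model(name, small_data)
        st = m.unpack(0.4 * rng.standard_normal(m.dim))
        eta0 = m.linear_predictor(st)
        st2 = recenter_effects(st)
        assert abs(np.mean(st2.params["a"])) < 1e-12
        assert np.allclose(m.linear_predictor(st2), eta0, atol=1e-12)
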