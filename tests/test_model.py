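"""Likelihood pieces, priors, the correlation-Cholesky machinery, and the
analytic gradients of the unconstrained posterior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from dyadmnl import (
    ModelSpec,
    Parameters,
    PriorConfig,
    category_probabilities,
    cholesky_from_corr,
    corr_from_cholesky,
    linear_predictor,
    log_likelihood_pointwise,
    log_prior,
)
from dyadmnl._posterior import Posterior
from dyadmnl.model import (
    cholesky_from_cpc,
    cpc_from_cholesky,
    lkj_cholesky_logpdf,
    sample_lkj_cholesky,
)


def make_params(spec, I, H, rng, zero=False):
    Kp, m = spec.K - 1, spec.n_covariates
    r = (lambda *s: np.zeros(s)) if zero else (lambda *s: rng.standard_normal(s))
    scale = (lambda k: np.zeros(k)) if zero else (lambda k: np.abs(rng.standard_normal(k)))
    L = np.eye(Kp) if zero else sample_lkj_cholesky(Kp, 2.0, rng)
    kw = dict(
        alpha=r(Kp), z_I=r(I, Kp), z_R=r(I, Kp),
        L_I=L.copy(), L_R=np.eye(Kp) if zero else sample_lkj_cholesky(Kp, 2.0, rng),
        sigma_I=scale(Kp), sigma_R=scale(Kp),
    )
    if spec.has_fixed:
        kw.update(beta_I=r(Kp, m), beta_R=r(Kp, m), beta_H=r(Kp))
    if spec.has_household:
        kw.update(
            z_hI=r(H, Kp), z_hR=r(H, Kp),
            L_hI=np.eye(Kp) if zero else sample_lkj_cholesky(Kp, 2.0, rng),
            L_hR=np.eye(Kp) if zero else sample_lkj_cholesky(Kp, 2.0, rng),
            sigma_hI=scale(Kp), sigma_hR=scale(Kp),
        )
    return Parameters(**kw)


class TestLinearPredictor:
    def test_all_zero_parameters_give_zero(self, k4_study):
        spec = ModelSpec(variant="ihF", K=4)
        data = k4_study["data"]
        p = make_params(spec, data.n_individuals, data.n_households, None, zero=True)
        eta = linear_predictor(p, data, spec)
        assert np.all(eta == 0.0)

    def test_intercept_only_propagates(self, k4_study):
        spec = ModelSpec(variant="i", K=4)
        data = k4_study["data"]
        p = make_params(spec, data.n_individuals, data.n_households, None, zero=True)
        p.alpha = np.array([1.0, 0.0, 0.0])
        eta = linear_predictor(p, data, spec)
        assert np.allclose(eta, np.tile([1.0, 0.0, 0.0], (data.n_events, 1)))

    def test_matches_term_by_term_summation(self, k4_study):
        """Vectorized predictor equals an explicit per-event loop over the
        model formula's terms."""
        spec = ModelSpec(variant="ihF", K=4)
        data = k4_study["data"]
        rng = np.random.default_rng(3)
        p = make_params(spec, data.n_individuals, data.n_households, rng)
        eta = linear_predictor(p, data, spec)
        nu_I, nu_R = p.nu("initiator"), p.nu("recipient")
        h_I, h_R = p.nu("household_initiator"), p.nu("household_recipient")
        for n in [0, 5, 17, data.n_events - 1]:
            for k in range(3):
                expected = (
                    p.alpha[k]
                    + nu_I[data.i_idx[n], k]
                    + nu_R[data.j_idx[n], k]
                    + h_I[data.hi_idx[n], k]
                    + h_R[data.hj_idx[n], k]
                    + sum(p.beta_I[k, m] * data.X_I[n, m] for m in range(3))
                    + sum(p.beta_R[k, m] * data.X_R[n, m] for m in range(3))
                    + p.beta_H[k] * data.x_H[n]
                )
                assert eta[n, k] == pytest.approx(expected, abs=1e-12)


class TestCategoryProbabilities:
    def test_uniform_at_zero(self):
        pi = category_probabilities(np.zeros(18))
        assert np.allclose(pi, 1.0 / 19, atol=1e-15)

    def test_log_odds_ratio_exact(self):
        eta = np.array([np.log(2.0), 0.0, 0.0])
        pi = category_probabilities(eta)
        assert pi[0] / pi[-1] == pytest.approx(2.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(arrays(float, 5, elements=st.floats(-30, 30)))
    def test_matches_bruteforce_and_sums_to_one(self, eta):
        pi = category_probabilities(eta)
        brute = np.exp(np.append(eta, 0.0))
        brute /= brute.sum()
        assert np.allclose(pi, brute, atol=1e-12)
        assert abs(pi.sum() - 1.0) < 1e-12
        assert np.all(pi > 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(float, 4, elements=st.floats(-10, 10)),
        st.floats(-5, 5),
    )
    def test_reference_invariance(self, eta, c):
        """Adding a constant to all K unnormalized log-scores leaves the
        simplex unchanged."""
        full = np.append(eta, 0.0) + c
        brute = np.exp(full - full.max())
        brute /= brute.sum()
        assert np.allclose(category_probabilities(eta), brute, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            category_probabilities(np.array([np.nan, 0.0]))


class TestPointwiseLoglik:
    def test_zero_params_give_log_1_over_19(self, k4_study):
        # embed the K=4 events in a K=19 taxonomy is not meaningful; build a
        # direct check instead on the fixture's own K
        spec = ModelSpec(variant="i", K=4)
        data = k4_study["data"]
        p = make_params(spec, data.n_individuals, data.n_households, None, zero=True)
        ll = log_likelihood_pointwise(p, data, spec)
        assert np.allclose(ll, np.log(1.0 / 4.0), atol=1e-12)

    def test_hand_computed_k3(self):
        """Two-event toy: categorical log-pmf computed by hand."""
        from types import SimpleNamespace

        from dyadmnl import BehaviorTaxonomy

        data = SimpleNamespace(
            y=np.array([0, 2]),
            i_idx=np.array([0, 1]),
            j_idx=np.array([1, 0]),
            hi_idx=np.array([0, 0]),
            hj_idx=np.array([0, 0]),
            X_I=np.zeros((2, 3)),
            X_R=np.zeros((2, 3)),
            x_H=np.ones(2),
            n_events=2,
            taxonomy=BehaviorTaxonomy.reduced(3),
        )
        spec = ModelSpec(variant="i", K=3)
        p = make_params(spec, 2, 1, None, zero=True)
        p.alpha = np.array([np.log(2.0), np.log(3.0)])
        # pi = (2, 3, 1)/6
        ll = log_likelihood_pointwise(p, data, spec)
        assert ll[0] == pytest.approx(np.log(2.0 / 6.0), abs=1e-12)
        assert ll[1] == pytest.approx(np.log(1.0 / 6.0), abs=1e-12)

    def test_identical_events_identical_values(self, k4_study):
        import dataclasses

        spec = ModelSpec(variant="iF", K=4)
        data = k4_study["data"]
        dup = dataclasses.replace(data)
        for name in ("y", "i_idx", "j_idx", "hi_idx", "hj_idx", "X_I", "X_R", "x_H"):
            arr = getattr(data, name).copy()
            arr[1] = arr[0]  # make event 1 a byte-for-byte copy of event 0
            setattr(dup, name, arr)
        rng = np.random.default_rng(8)
        p = make_params(spec, data.n_individuals, data.n_households, rng)
        ll = log_likelihood_pointwise(p, dup, spec)
        assert ll[0] == ll[1]


class TestCholeskyAndLkj:
    def test_corr_round_trip(self):
        R = np.array([[1.0, 0.5, -0.2], [0.5, 1.0, 0.1], [-0.2, 0.1, 1.0]])
        L = cholesky_from_corr(R)
        assert np.allclose(corr_from_cholesky(L), R, atol=1e-10)

    def test_cpc_round_trip(self):
        rng = np.random.default_rng(0)
        L = sample_lkj_cholesky(5, 2.0, rng)
        z = cpc_from_cholesky(L)
        assert np.allclose(cholesky_from_cpc(z), L, atol=1e-12)

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 0.99], [0.99, 1.0]])
        R[0, 1] = R[1, 0] = 1.2
        with pytest.raises(ValueError):
            cholesky_from_corr(R)

    def test_lkj_density_matches_row_kernel(self):
        """The CPC-based density differs from the standard per-row kernel
        sum_k (d-k+2*shape-3) log L_kk only by a constant."""
        rng = np.random.default_rng(1)
        d, shape = 4, 2.0
        diffs = []
        for _ in range(5):
            L = sample_lkj_cholesky(d, shape, rng)
            kernel = sum(
                (d - (i + 1) + 2 * shape - 2) * np.log(L[i, i]) for i in range(1, d)
            )
            diffs.append(lkj_cholesky_logpdf(L, shape) - kernel)
        assert np.ptp(diffs) < 1e-10

    def test_lkj_marginal_distribution(self):
        """Off-diagonal elements of LKJ(shape) correlation matrices follow
        2 Beta(shape-1+d/2, shape-1+d/2) - 1."""
        rng = np.random.default_rng(7)
        d, shape = 4, 2.0
        rhos = [corr_from_cholesky(sample_lkj_cholesky(d, shape, rng))[2, 0] for _ in range(2000)]
        b = shape - 1 + d / 2
        p = stats.kstest((np.array(rhos) + 1) / 2, "beta", args=(b, b)).pvalue
        assert p > 1e-3


class TestLogPrior:
    def test_standard_normal_intercept_term(self):
        spec = ModelSpec(variant="i", K=2, priors=PriorConfig())
        p = Parameters(
            alpha=np.zeros(1), z_I=np.zeros((1, 1)), z_R=np.zeros((1, 1)),
            L_I=np.ones((1, 1)), L_R=np.ones((1, 1)),
            sigma_I=np.zeros(1), sigma_R=np.zeros(1),
        )
        base = log_prior(p, spec)
        p2 = Parameters(
            alpha=np.ones(1), z_I=np.zeros((1, 1)), z_R=np.zeros((1, 1)),
            L_I=np.ones((1, 1)), L_R=np.ones((1, 1)),
            sigma_I=np.zeros(1), sigma_R=np.zeros(1),
        )
        assert base - log_prior(p2, spec) == pytest.approx(0.5, abs=1e-12)

    def test_lkj_shape_touches_only_L_terms(self):
        rng = np.random.default_rng(2)
        spec_a = ModelSpec(variant="i", K=4, priors=PriorConfig(lkj_shape=2.0))
        spec_b = ModelSpec(variant="i", K=4, priors=PriorConfig(lkj_shape=4.0))
        p = make_params(spec_a, 3, 2, rng)
        diff = log_prior(p, spec_a) - log_prior(p, spec_b)
        expected = (
            lkj_cholesky_logpdf(p.L_I, 2.0) + lkj_cholesky_logpdf(p.L_R, 2.0)
            - lkj_cholesky_logpdf(p.L_I, 4.0) - lkj_cholesky_logpdf(p.L_R, 4.0)
        )
        assert diff == pytest.approx(expected, abs=1e-10)

    def test_term_by_term_oracle_k3(self):
        """Full prior at a fixed K=3 point vs an independent scipy.stats
        summation."""
        rng = np.random.default_rng(4)
        spec = ModelSpec(variant="iF", K=3, priors=PriorConfig())
        p = make_params(spec, 2, 1, rng)
        expected = 0.0
        for block in (p.alpha, p.beta_I, p.beta_R, p.beta_H, p.z_I, p.z_R):
            expected += stats.norm.logpdf(np.ravel(block)).sum()
        for sig in (p.sigma_I, p.sigma_R):
            expected += stats.halfnorm.logpdf(sig).sum()
        for L in (p.L_I, p.L_R):
            expected += lkj_cholesky_logpdf(L, 2.0)
        assert log_prior(p, spec) == pytest.approx(expected, abs=1e-10)


class TestNonCenteredEquivalence:
    def test_simulated_covariance_matches_target(self):
        """nu = z (D L)' has covariance D L L' D."""
        rng = np.random.default_rng(9)
        L = sample_lkj_cholesky(3, 2.0, rng)
        sigma = np.array([0.5, 1.0, 1.5])
        A = sigma[:, None] * L
        z = rng.standard_normal((100_000, 3))
        nu = z @ A.T
        target = np.diag(sigma) @ L @ L.T @ np.diag(sigma)
        assert np.allclose(np.cov(nu.T), target, atol=0.03)

    def test_same_household_children_share_h_terms(self, k4_study):
        spec = ModelSpec(variant="ih", K=4)
        data = k4_study["data"]
        rng = np.random.default_rng(10)
        p = make_params(spec, data.n_individuals, data.n_households, rng)
        h = p.nu("household_initiator")
        same = data.hi_idx[0]
        rows = np.where(data.hi_idx == same)[0]
        assert len(rows) > 1
        eta = linear_predictor(p, data, spec)
        # subtracting individual terms leaves identical household+fixed parts
        nu_I, nu_R = p.nu("initiator"), p.nu("recipient")
        resid = eta - nu_I[data.i_idx] - nu_R[data.j_idx] - p.nu("household_recipient")[data.hj_idx]
        assert np.allclose(resid[rows] - p.alpha, h[same], atol=1e-12)


def test_variant_i_is_iF_with_zero_betas(k4_study):
    data = k4_study["data"]
    rng = np.random.default_rng(11)
    spec_iF = ModelSpec(variant="iF", K=4)
    p = make_params(spec_iF, data.n_individuals, data.n_households, rng)
    p.beta_I[:] = 0.0
    p.beta_R[:] = 0.0
    p.beta_H[:] = 0.0
    spec_i = ModelSpec(variant="i", K=4)
    ll_iF = log_likelihood_pointwise(p, data, spec_iF)
    ll_i = log_likelihood_pointwise(p, data, spec_i)
    assert np.array_equal(ll_iF, ll_i)


@pytest.mark.parametrize("variant", ["i", "iF", "ih", "ihF"])
def test_gradient_matches_finite_differences(k4_study, variant):
    """Analytic gradient of the unconstrained log posterior vs central
    finite differences, for every variant."""
    data = k4_study["data"]
    post = Posterior(ModelSpec(variant=variant, K=4), data)
    rng = np.random.default_rng(12)
    theta = post.initial_position(rng)
    lp, grad = post.logp_grad(theta)
    assert np.isfinite(lp)
    eps = 1e-6
    idx = rng.choice(post.dim, size=min(30, post.dim), replace=False)
    for i in idx:
        t1, t2 = theta.copy(), theta.copy()
        t1[i] += eps
        t2[i] -= eps
        fd = (post.logp(t1) - post.logp(t2)) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_internal_density_decomposition(k4_study):
    """Posterior.logp equals public log_prior + total log-likelihood plus
    the exact change-of-variables terms of the sigma and L transforms."""
    data = k4_study["data"]
    spec = ModelSpec(variant="ihF", K=4)
    post = Posterior(spec, data)
    rng = np.random.default_rng(13)
    theta = post.initial_position(rng)
    lp, _ = post.logp_grad(theta)
    params = post.constrain(theta)
    expected = log_prior(params, spec) + log_likelihood_pointwise(params, data, spec).sum()
    for name in ("s_I", "s_R", "s_hI", "s_hR"):
        expected += theta[post.slices[name]].sum()
    for L in (params.L_I, params.L_R, params.L_hI, params.L_hR):
        z = cpc_from_cholesky(L)
        d = L.shape[0]
        for i in range(1, d):
            for j in range(i):
                expected += ((i - 1 - j) / 2 + 1) * np.log1p(-z[i, j] ** 2)
    assert lp == pytest.approx(expected, abs=1e-8)


def test_spec_validation_and_yaml_round_trip(tmp_path):
    with pytest.raises(ValueError):
        ModelSpec(variant="x", K=4)
    with pytest.raises(ValueError):
        ModelSpec(variant="iF", K=4, n_covariates=0)
    with pytest.raises(ValueError):
        PriorConfig(intercept_sd=-1.0)
    spec = ModelSpec(variant="ihF", K=8, priors=PriorConfig(lkj_shape=3.0))
    spec.to_yaml(tmp_path / "spec.yaml")
    assert ModelSpec.from_yaml(tmp_path / "spec.yaml") == spec
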