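import numpy as np
import pytest
import scipy.stats as st

from conftest import make_params, make_subject
from oracles import gh_loglik_oracle

from flexjm.data import SubjectRecord
from flexjm.likelihood import (
    LikelihoodCore,
    build_probit_system,
    build_sigma,
    dataset_loglik,
    gaussian_conjugacy,
    mvn_cdf,
    penalized_negloglik,
    penalty,
    subject_loglik,
)
from flexjm.timegrid import TimePartition, association_design, intercept_map


class TestBuildSigma:
    def test_identity_case(self, part3):
        p = make_params(part3.M, sigma0=1.0, sigma1=1.0, sigma2=1.0, rho=1e-12)
        np.testing.assert_allclose(build_sigma(p, part3.M).Sigma, np.eye(4), atol=1e-10)

    def test_block_structure(self, part3, rng):
        p = make_params(part3.M, sigma0=1.3, sigma1=0.7, sigma2=0.4, rho=-0.5)
        S = build_sigma(p, part3.M).Sigma
        np.testing.assert_allclose(S[0, 1], -0.5 * 1.3 * 0.7)
        np.testing.assert_allclose(S[2:, 2:], 0.16 * np.eye(2))
        assert np.all(S[2:, :2] == 0)
        np.testing.assert_array_equal(S, S.T)
        assert np.all(np.linalg.eigvalsh(S) > 0)

    def test_induced_covariance_w10_w20(self, rng):
        # cov(W_10, W_20) = sigma0^2 + k1 rho sigma0 sigma1
        for _ in range(10):
            k1 = rng.uniform(0.05, 0.5)
            part = TimePartition(np.array([0.0, k1, 1.0]))
            p = make_params(
                part.M,
                sigma0=rng.uniform(0.2, 2),
                sigma1=rng.uniform(0.2, 2),
                sigma2=rng.uniform(0.2, 2),
                rho=rng.uniform(-0.9, 0.9),
                beta=np.zeros(part.M + 1),
            )
            S = build_sigma(p, part.M).Sigma
            w1, w2 = intercept_map(1, part), intercept_map(2, part)
            expected = p.sigma0**2 + k1 * p.rho * p.sigma0 * p.sigma1
            assert w1 @ S @ w2 == pytest.approx(expected, rel=1e-12)

    def test_induced_covariance_w20_w30(self, rng):
        # cov(W_20, W_30) = sigma0^2 + k1 k2 sigma1^2 + (k1+k2) rho sigma0 sigma1
        for _ in range(10):
            k1 = rng.uniform(0.05, 0.4)
            k2 = k1 + rng.uniform(0.05, 0.4)
            part = TimePartition(np.array([0.0, k1, k2, 1.0]))
            p = make_params(
                part.M,
                sigma0=rng.uniform(0.2, 2),
                sigma1=rng.uniform(0.2, 2),
                sigma2=rng.uniform(0.2, 2),
                rho=rng.uniform(-0.9, 0.9),
                beta=np.zeros(part.M + 1),
            )
            S = build_sigma(p, part.M).Sigma
            w2, w3 = intercept_map(2, part), intercept_map(3, part)
            expected = (
                p.sigma0**2
                + k1 * k2 * p.sigma1**2
                + (k1 + k2) * p.rho * p.sigma0 * p.sigma1
            )
            assert w2 @ S @ w3 == pytest.approx(expected, rel=1e-12)

    def test_invalid_M(self, part3):
        with pytest.raises(ValueError):
            build_sigma(make_params(part3.M), 0)


class TestGaussianConjugacy:
    def test_no_data_returns_prior(self, part3):
        p = make_params(part3.M)
        s = SubjectRecord(
            id=0, times=np.empty(0), y=np.empty(0), x_long=np.empty((0, 0)),
            s_star=1, delta=0,
        )
        conj = gaussian_conjugacy(s, p, part3)
        np.testing.assert_array_equal(conj.mu_post, 0.0)
        np.testing.assert_array_equal(conj.Sigma_post, build_sigma(p, part3.M).Sigma)
        assert conj.log_marginal_y == 0.0

    def test_uninformative_limit(self, part3, rng):
        base = make_params(part3.M)
        s = make_subject(part3, base, rng)
        p = make_params(part3.M, sigma_eps=1e8)
        conj = gaussian_conjugacy(s, p, part3)
        np.testing.assert_allclose(conj.mu_post, 0.0, atol=1e-9)
        np.testing.assert_allclose(
            conj.Sigma_post, build_sigma(p, part3.M).Sigma, atol=1e-9
        )

    def test_bayes_identity(self, part3, rng):
        # f(Y) N(b; mu_post, Sig_post) must equal N(Y; .) N(b; 0, Sigma)
        p = make_params(part3.M, rng=rng)
        s = make_subject(part3, p, rng)
        conj = gaussian_conjugacy(s, p, part3)
        Sigma = build_sigma(p, part3.M).Sigma
        from flexjm.timegrid import design_matrix

        B = design_matrix(s.times, part3).values
        for _ in range(20):
            b = rng.normal(size=part3.M + 1)
            lhs = conj.log_marginal_y + st.multivariate_normal.logpdf(
                b, conj.mu_post, conj.Sigma_post, allow_singular=True
            )
            rhs = st.multivariate_normal.logpdf(
                s.y, B @ (p.beta), np.eye(s.n_obs) * p.sigma_eps**2
            )
            # f(Y | b) with mean shifted by B b
            rhs = st.norm.logpdf(s.y, B @ (p.beta + b), p.sigma_eps).sum()
            rhs += st.multivariate_normal.logpdf(b, np.zeros(part3.M + 1), Sigma)
            assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_nonfinite_y_raises(self, part3, rng):
        p = make_params(part3.M)
        s = make_subject(part3, p, rng)
        s.y[0] = np.nan
        with pytest.raises(FloatingPointError):
            gaussian_conjugacy(s, p, part3)


class TestProbitSystem:
    def test_zero_gamma(self, part3, rng):
        p = make_params(part3.M, gamma=np.zeros(2))
        s = make_subject(part3, p, rng, s_star=2, delta=0)
        sys = build_probit_system(s, p, part3)
        np.testing.assert_array_equal(sys.loadings, 0.0)
        np.testing.assert_allclose(sys.offsets, s.x_surv[:2] @ p.alpha_tilde)
        np.testing.assert_array_equal(sys.signs, [1.0, 1.0])

    def test_event_first_interval_sign(self, part3, rng):
        p = make_params(part3.M)
        s = make_subject(part3, p, rng, s_star=1, delta=1)
        sys = build_probit_system(s, p, part3)
        assert sys.signs.shape == (1,)
        assert sys.signs[0] == -1.0

    def test_loadings_are_gamma_weighted_maps(self, part3, rng):
        from flexjm.timegrid import intercept_map, slope_map

        p = make_params(part3.M, rng=rng)
        s = make_subject(part3, p, rng, s_star=3, delta=0)
        sys = build_probit_system(s, p, part3)
        for k in range(1, 4):
            expected = p.gamma[0] * intercept_map(k, part3) + p.gamma[1] * slope_map(
                k, part3
            )
            np.testing.assert_allclose(sys.loadings[k - 1], expected)

    def test_loadings_match_finite_difference(self, part3, rng):
        # derivative of the survival linear predictor in b
        p = make_params(part3.M, rng=rng)
        s = make_subject(part3, p, rng, s_star=2, delta=0)
        sys = build_probit_system(s, p, part3)
        h = 1e-6
        for k in range(1, 3):
            A = association_design(k, part3)
            for j in range(part3.M + 1):
                b0 = np.zeros(part3.M + 1)
                b1 = b0.copy()
                b1[j] += h
                eta0 = p.gamma @ A @ (p.beta + b0)
                eta1 = p.gamma @ A @ (p.beta + b1)
                assert sys.loadings[k - 1, j] == pytest.approx(
                    (eta1 - eta0) / h, abs=1e-5
                )

    def test_interval_specific_gamma(self, part3, rng):
        gam = rng.normal(size=(part3.M, 2))
        p = make_params(part3.M, gamma=gam)
        s = make_subject(part3, p, rng, s_star=3, delta=0)
        sys = build_probit_system(s, p, part3)
        for k in range(1, 4):
            A = association_design(k, part3)
            np.testing.assert_allclose(sys.loadings[k - 1], gam[k - 1] @ A)

    def test_missing_covariates_raise(self, part3, rng):
        p = make_params(part3.M)
        s = make_subject(part3, p, rng, s_star=2, delta=0)
        s.x_surv = s.x_surv[:1]
        with pytest.raises(ValueError, match="covariates"):
            build_probit_system(s, p, part3)


class TestMvnCdf:
    def test_univariate_median(self):
        assert mvn_cdf([0.0], [[1.0]]) == pytest.approx(0.5, abs=1e-12)

    def test_bivariate_independence(self):
        assert mvn_cdf([0.0, 0.0], np.eye(2)) == pytest.approx(0.25, rel=1e-5)

    def test_bivariate_orthant_closed_form(self):
        # P(Z1<=0, Z2<=0) = 1/4 + asin(rho)/(2 pi)
        for rho in (-0.7, -0.2, 0.5, 0.9):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            expected = 0.25 + np.arcsin(rho) / (2 * np.pi)
            assert mvn_cdf([0.0, 0.0], cov) == pytest.approx(expected, rel=2e-5)
        assert mvn_cdf([0.0, 0.0], [[1, 0.5], [0.5, 1]]) == pytest.approx(
            1 / 3, rel=2e-5
        )

    def test_empty_problem_returns_one(self):
        assert mvn_cdf(np.empty(0), np.empty((0, 0))) == 1.0

    def test_against_scipy(self, rng):
        for K in (3, 4, 6):
            A = rng.standard_normal((K, K))
            cov = A @ A.T + K * np.eye(K)
            u = rng.standard_normal(K) * np.sqrt(np.diag(cov))
            ref = st.multivariate_normal.cdf(u, mean=np.zeros(K), cov=cov)
            assert mvn_cdf(u, cov) == pytest.approx(ref, rel=5e-4)

    def test_determinism(self, rng):
        cov = np.array([[2.0, 0.3, 0.1], [0.3, 1.0, -0.2], [0.1, -0.2, 1.5]])
        u = np.array([0.3, -0.5, 1.0])
        assert mvn_cdf(u, cov) == mvn_cdf(u, cov)

    def test_asymmetric_cov_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            mvn_cdf([0.0, 0.0], [[1.0, 0.5], [0.1, 1.0]])


class TestSubjectLoglik:
    def test_zero_gamma_factorizes(self, part3, rng):
        from scipy.special import log_ndtr

        p = make_params(part3.M, gamma=np.zeros(2), rng=rng)
        s = make_subject(part3, p, rng, s_star=2, delta=1)
        conj = gaussian_conjugacy(s, p, part3)
        eta = s.x_surv[:2] @ p.alpha_tilde
        expected = (
            conj.log_marginal_y + log_ndtr(eta[0]) + log_ndtr(-eta[1])
        )
        assert subject_loglik(s, p, part3) == pytest.approx(expected, abs=1e-9)

    def test_survival_only_subject(self, part3):
        from scipy.special import log_ndtr

        p = make_params(part3.M, gamma=np.zeros(2))
        s = SubjectRecord(
            id=0, times=np.empty(0), y=np.empty(0), x_long=np.empty((0, 0)),
            s_star=1, delta=0,
            x_surv=np.column_stack([np.ones(3), part3.boundaries[:-1]]),
        )
        expected = log_ndtr(s.x_surv[0] @ p.alpha_tilde)
        assert subject_loglik(s, p, part3) == pytest.approx(float(expected), abs=1e-9)

    def test_matches_quadrature_oracle(self, part3, rng):
        # M=3, b is 4-dimensional: tensor quadrature over b
        p = make_params(part3.M, rng=rng)
        for delta in (0, 1):
            s = make_subject(part3, p, rng, n_obs=2, s_star=2, delta=delta)
            ll = subject_loglik(s, p, part3)
            oracle = gh_loglik_oracle(s, p, part3, n_nodes=15)
            assert np.exp(ll) == pytest.approx(np.exp(oracle), rel=1e-5)

    def test_reordering_invariance(self, part3, rng):
        p = make_params(part3.M, rng=rng)
        s = make_subject(part3, p, rng, n_obs=4, s_star=3, delta=0)
        perm = rng.permutation(4)
        s2 = SubjectRecord(
            id=0, times=s.times[perm], y=s.y[perm], x_long=s.x_long[perm],
            s_star=s.s_star, delta=s.delta, x_surv=s.x_surv,
        )
        assert subject_loglik(s2, p, part3) == pytest.approx(
            subject_loglik(s, p, part3), abs=1e-9
        )

    def test_monotone_in_gamma_for_survivors(self, part3, rng):
        # all-positive association terms fixed: larger gamma -> larger
        # survival factors for a censored subject
        from scipy.special import ndtr

        beta = np.array([1.0, 0.5, 0.3, 0.2])  # positive value and slope everywhere
        lls = []
        for scale in (0.1, 0.5, 1.0):
            p = make_params(part3.M, beta=beta, gamma=np.array([0.4, 0.2]) * scale)
            s = SubjectRecord(
                id=0, times=np.empty(0), y=np.empty(0), x_long=np.empty((0, 0)),
                s_star=3, delta=0,
                x_surv=np.column_stack([np.ones(3), part3.boundaries[:-1]]),
            )
            lls.append(subject_loglik(s, p, part3))
        assert lls[0] < lls[1] < lls[2]

    def test_reduction_to_linear_basis(self, part3, rng):
        """Full basis with sigma2 -> 0 must agree with the 2-column random
        intercept+slope path to near machine precision, and both with an
        independent quadrature evaluation of the linear model."""
        beta_lin = np.array([0.4, -0.8])
        p_full = make_params(
            part3.M,
            beta=np.concatenate([beta_lin, np.zeros(part3.M - 1)]),
            gamma=np.array([0.5, 0.3]),
            sigma2=1e-9,
        )
        p_lin = make_params(
            part3.M, beta=beta_lin, gamma=np.array([0.5, 0.3]), sigma2=None
        )
        s = make_subject(part3, make_params(part3.M, rng=rng), rng, s_star=2, delta=1)
        ll_full = subject_loglik(s, p_full, part3)
        core_lin = _single_subject_core(s, part3, n_basis=2)
        ll_lin = core_lin.subject_logliks(p_lin)[0]
        assert ll_full == pytest.approx(ll_lin, abs=1e-10)
        ll_ref = _linear_model_loglik(s, p_lin, part3)
        assert np.exp(ll_lin) == pytest.approx(np.exp(ll_ref), rel=1e-4)


def _single_subject_core(subject, part, n_basis):
    from flexjm.data import JointDataset

    ds = JointDataset(subjects=[subject], partition=part)
    return LikelihoodCore(ds, n_basis=n_basis, n_points=8192)


def _linear_model_loglik(subject, params, part):
    """Independent quadrature evaluation for the random intercept+slope model."""
    from scipy.special import logsumexp, ndtr

    nodes, weights = np.polynomial.hermite.hermgauss(60)
    Sigma = np.array(
        [
            [params.sigma0**2, params.rho * params.sigma0 * params.sigma1],
            [params.rho * params.sigma0 * params.sigma1, params.sigma1**2],
        ]
    )
    B = np.column_stack([np.ones(subject.n_obs), subject.times])
    # importance centering at the ridge posterior of the longitudinal part
    prec = np.linalg.inv(Sigma) + B.T @ B / params.sigma_eps**2
    cov = np.linalg.inv(prec) * 1.7
    mean = (
        np.linalg.inv(prec) @ (B.T @ (subject.y - B @ params.beta))
        / params.sigma_eps**2
    )
    C = np.linalg.cholesky(cov)
    Z = np.column_stack([g.ravel() for g in np.meshgrid(nodes, nodes, indexing="ij")])
    logW = np.sum(
        np.log(np.array(np.meshgrid(weights, weights, indexing="ij"))).reshape(2, -1).T,
        axis=1,
    )
    bs = mean + np.sqrt(2.0) * Z @ C.T
    def logpdf2(x, m, S):
        L = np.linalg.cholesky(S)
        r = np.linalg.solve(L, (x - m).T).T
        return -np.log(2 * np.pi) - np.sum(np.log(np.diag(L))) - 0.5 * np.sum(r * r, axis=1)

    mu = B @ params.beta + bs @ B.T
    ll = np.sum(
        -0.5 * np.log(2 * np.pi * params.sigma_eps**2)
        - 0.5 * ((subject.y - mu) / params.sigma_eps) ** 2,
        axis=1,
    )
    ll = ll + logpdf2(bs, np.zeros(2), Sigma) - logpdf2(bs, mean, cov)
    for r in range(1, subject.s_star + 1):
        k = part.boundaries[r - 1]
        m_val = params.beta[0] + bs[:, 0] + (params.beta[1] + bs[:, 1]) * k
        m_slope = params.beta[1] + bs[:, 1]
        eta = subject.x_surv[r - 1] @ params.alpha_tilde + params.gamma @ np.vstack(
            [m_val, m_slope]
        )
        sign = -1.0 if (r == subject.s_star and subject.delta == 1) else 1.0
        ll = ll + np.log(ndtr(sign * eta))
    return float(logsumexp(logW + ll) - np.log(np.pi))


class TestPenalizedObjective:
    def test_zero_lambda_is_plain_negloglik(self, part3, rng, demo_data):
        cfg, ds, _ = demo_data
        p = cfg.true_params
        assert penalized_negloglik(p, 0.0, ds) == pytest.approx(
            -dataset_loglik(ds, p), abs=1e-9
        )

    def test_zero_btilde_no_penalty(self, part3):
        p = make_params(part3.M, beta=np.array([1.0, -2.0, 0.0, 0.0]))
        assert penalty(p, 17.3) == 0.0

    def test_penalty_arithmetic(self, part3):
        p = make_params(part3.M, beta=np.array([1.0, -2.0, 0.7, 0.0]))
        assert penalty(p, 2.0) == pytest.approx(2.0 * 0.49)

    def test_negative_lambda_rejected(self, part3):
        p = make_params(part3.M)
        with pytest.raises(ValueError):
            penalty(p, -1.0)


class TestLikelihoodCore:
    def test_matches_per_subject_path(self, demo_data):
        cfg, ds, _ = demo_data
        core = LikelihoodCore(ds, n_points=8192)
        batch = core.subject_logliks(cfg.true_params)
        for i in (0, 3, 11, 40):
            ref = subject_loglik(ds.subjects[i], cfg.true_params, ds.partition)
            assert batch[i] == pytest.approx(ref, abs=2e-5)

    def test_total_consistency(self, demo_data):
        cfg, ds, _ = demo_data
        core = LikelihoodCore(ds, n_points=8192)
        assert core.loglik(cfg.true_params) == pytest.approx(
            dataset_loglik(ds, cfg.true_params), abs=1e-3
        )
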