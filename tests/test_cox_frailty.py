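"""Cox partial likelihood, frailty Laplace approximation, and naive fits."""

import itertools

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import roots_hermite

from mebn import (
    CorrelationModel,
    SurvivalData,
    fit_cox_frailty,
    fit_cox_iid,
    kinship_from_pedigree,
    make_synthetic_cohort,
    penalized_partial_loglik,
    simulate_survival_trait,
)
from mebn.cox_frailty import CoxFrailtyScorer, CoxPartial


def hand_partial_loglik(time, event, eta):
    """Risk-set enumeration oracle (Breslow)."""
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = np.flatnonzero(time >= time[i])
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


class TestPartialLoglik:
    def test_three_subject_hand_computation(self):
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 1, 0])
        eta = np.array([0.2, -0.1, 0.4])
        cp = CoxPartial(time, event)
        expected = (eta[0] - np.log(np.exp(eta).sum())) + (
            eta[1] - np.log(np.exp(eta[1]) + np.exp(eta[2]))
        )
        assert cp.loglik(eta) == pytest.approx(expected, abs=1e-12)
        assert cp.loglik(eta) == pytest.approx(hand_partial_loglik(time, event, eta))

    def test_matches_enumeration_oracle_with_ties(self, rng):
        n = 25
        time = rng.integers(1, 8, n).astype(float)  # many ties
        event = rng.integers(0, 2, n)
        event[0] = 1
        eta = rng.standard_normal(n)
        cp = CoxPartial(time, event)
        assert cp.loglik(eta) == pytest.approx(hand_partial_loglik(time, event, eta))

    def test_gradient_and_hessian_match_finite_differences(self, rng):
        n = 12
        time = np.sort(rng.uniform(0.1, 3, n))
        event = rng.integers(0, 2, n)
        event[-1] = 1
        eta = 0.3 * rng.standard_normal(n)
        cp = CoxPartial(time, event)
        g = cp.grad(eta)
        H = cp.neg_hessian(eta)
        eps = 1e-6
        for i in range(n):
            e = np.zeros(n)
            e[i] = eps
            gi = (cp.loglik(eta + e) - cp.loglik(eta - e)) / (2 * eps)
            assert g[i] == pytest.approx(gi, abs=1e-5)
            hrow = -(cp.grad(eta + e) - cp.grad(eta - e)) / (2 * eps)
            assert np.allclose(H[i], hrow, atol=1e-5)

    def test_penalty_vanishes_at_zero_frailty(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 1, 1])
        X = np.array([[0.0], [1.0], [1.0], [0.0]])
        data = SurvivalData(time, event, X)
        A = np.eye(4)
        beta = np.array([0.7])
        val = penalized_partial_loglik(data, beta, np.zeros(4), 1.0, A)
        assert val == pytest.approx(hand_partial_loglik(time, event, X @ beta))

    def test_permutation_invariance_with_structure(self, rng):
        K = kinship_from_pedigree(make_synthetic_cohort(2))
        n = K.n
        data = simulate_survival_trait(K, 1.0, [0.5], rng.standard_normal((n, 1)), seed=1)
        R = rng.standard_normal(n) * 0.3
        beta = np.array([0.5])
        a = penalized_partial_loglik(data, beta, R, 1.2, K.full())
        perm = rng.permutation(n)
        data_p = SurvivalData(data.time[perm], data.event[perm], data.X[perm])
        b = penalized_partial_loglik(data_p, beta, R[perm], 1.2, K.full()[np.ix_(perm, perm)])
        assert a == pytest.approx(b, abs=1e-9)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            CoxPartial(np.array([1.0, 2.0]), np.array([0, 0]))


def gauss_hermite_marginal_loglik(time, event, X, beta, gamma2, clusters, nodes=13):
    """Adaptive tensor-product Gauss-Hermite oracle for shared exchangeable
    frailty: one frailty value per cluster, integrated exactly up to
    quadrature error.  Feasible only for a handful of small clusters."""
    labels = np.unique(clusters)
    m = labels.size
    Z = (clusters[:, None] == labels[None, :]).astype(float)
    eta_fix = X @ beta if beta.size else np.zeros(len(time))

    def pll(b):
        return hand_partial_loglik(time, event, eta_fix + Z @ b)

    def neg_obj(b):
        return -(pll(b) - 0.5 * (b @ b) / gamma2)

    # mode and curvature for adaptive centering
    from scipy.optimize import minimize
    res = minimize(neg_obj, np.zeros(m), method="BFGS")
    mode = res.x
    eps = 1e-4
    Hd = np.zeros(m)
    for j in range(m):
        e = np.zeros(m)
        e[j] = eps
        Hd[j] = (neg_obj(mode + e) - 2 * neg_obj(mode) + neg_obj(mode - e)) / eps**2
    scale = 1.0 / np.sqrt(np.maximum(Hd, 1e-8))
    x, w = roots_hermite(nodes)
    logw = np.log(w)
    total = -np.inf
    for combo in itertools.product(range(nodes), repeat=m):
        b = mode + np.sqrt(2.0) * scale * x[list(combo)]
        logf = pll(b) - 0.5 * (b @ b) / gamma2  # log integrand (unnormalized)
        lw = sum(logw[list(combo)]) + (x[list(combo)] ** 2).sum()
        total = np.logaddexp(total, logf + lw)
    total += np.sum(np.log(np.sqrt(2.0) * scale)) - 0.5 * m * np.log(2 * np.pi * gamma2)
    return float(total)


class TestFrailtyFit:
    def test_null_frailty_limit_recovers_standard_cox(self, rng):
        n = 60
        X = rng.standard_normal((n, 1))
        T = rng.exponential(np.exp(-0.6 * X[:, 0]))
        data = SurvivalData(T, np.ones(n, dtype=int), X)
        iid = fit_cox_iid(data)
        sc = CoxFrailtyScorer(data, np.eye(n))
        ll, beta, _ = sc._laplace((0,), 1e-8)
        assert beta[0] == pytest.approx(iid.beta[0], abs=1e-4)
        assert ll == pytest.approx(iid.loglik, abs=1e-4)

    def test_laplace_matches_gauss_hermite_on_small_clusters(self, rng):
        # 4 exchangeable clusters of size 3: 4-dimensional exact integral
        clusters = np.repeat(np.arange(4), 3)
        n = 12
        b_true = rng.standard_normal(4) * 0.7
        X = rng.standard_normal((n, 1))
        T = 2 * np.sqrt(rng.exponential(size=n) * np.exp(-(0.4 * X[:, 0] + b_true[clusters])))
        data = SurvivalData(T, np.ones(n, dtype=int), X)
        A = (clusters[:, None] == clusters[None, :]).astype(float)
        gamma2 = 0.5
        sc = CoxFrailtyScorer(data, A)
        ll_laplace, beta, _ = sc._laplace((0,), gamma2)
        ll_ghq = gauss_hermite_marginal_loglik(
            data.time, data.event, X, beta, gamma2, clusters
        )
        assert ll_laplace == pytest.approx(ll_ghq, abs=0.1)

    def test_positive_frailty_variance_recovered(self):
        # moderate frailty: gamma2-hat > 0 in the majority of seeds
        K = kinship_from_pedigree(make_synthetic_cohort(30))
        corr = CorrelationModel.from_kinship(K)
        positive = 0
        seeds = 12
        for seed in range(seeds):
            data = simulate_survival_trait(K, 1.0, np.zeros(0), np.empty((K.n, 0)), seed=seed)
            m = fit_cox_frailty(data, corr, gamma2_tol=1e-3)
            positive += m.gamma2 > 0.05
        assert positive > seeds / 2

    def test_adding_covariate_never_decreases_integrated_loglik(self, rng):
        K = kinship_from_pedigree(make_synthetic_cohort(15))
        corr = CorrelationModel.from_kinship(K)
        X = rng.standard_normal((K.n, 2))
        data = simulate_survival_trait(K, 1.0, [0.3, 0.0], X, seed=5)
        sc = CoxFrailtyScorer(data, corr, gamma2_tol=1e-3)
        ll0 = sc.fit(()).loglik
        ll1 = sc.fit((0,)).loglik
        ll2 = sc.fit((0, 1)).loglik
        assert ll1 >= ll0 - 1e-4
        assert ll2 >= ll1 - 1e-4


class TestNaiveCox:
    def test_hand_worked_binary_covariate_matches_score_root(self):
        # 4 subjects, all events: solve the score equation by bisection
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        data = SurvivalData(time, event, x[:, None])
        m = fit_cox_iid(data)

        def score(b):
            cp = CoxPartial(time, event)
            eps = 1e-6
            return (cp.loglik(x * (b + eps)) - cp.loglik(x * (b - eps))) / (2 * eps)

        root = brentq(score, -5, 5)
        assert m.beta[0] == pytest.approx(root, abs=1e-5)

    def test_null_covariate_estimates_near_zero(self, rng):
        n = 600
        X = rng.standard_normal((n, 1))
        T = rng.exponential(size=n)
        data = SurvivalData(T, np.ones(n, dtype=int), X)
        m = fit_cox_iid(data)
        assert abs(m.beta[0]) < 0.15

    def test_matches_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 150
        X = rng.standard_normal((n, 2))
        T = rng.exponential(np.exp(-(X @ [0.5, -0.4])))
        C = rng.uniform(0, 2.5, n)
        data = SurvivalData(np.minimum(T, C), (T <= C).astype(int), X)
        m = fit_cox_iid(data)
        df = pd.DataFrame({"t": data.time, "d": data.event,
                           "x1": X[:, 0], "x2": X[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "d")
        assert np.allclose(m.beta, ref.params_.values, atol=1e-5)
        assert m.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_no_events_rejected(self):
        data = SurvivalData(np.array([1.0, 2.0]), np.array([0, 0]), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            fit_cox_iid(data)
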