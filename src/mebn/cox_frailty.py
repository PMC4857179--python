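"""Cox proportional-hazards nodes with correlated log-normal frailty.

A survival node has hazard :math:`\\lambda(t) = \\lambda_0(t) \\exp(X\\beta + R)`
where the frailty vector ``R`` is multivariate normal on the log-hazard
scale with covariance ``gamma2 * A`` and ``A`` the (block-diagonal) additive
relationship or cluster-structure matrix.  Inference uses the penalized
partial likelihood: for fixed ``gamma2`` the mode of

.. math:: \\ell_p(\\beta, R) = \\ell_{cox}(X\\beta + R)
          - \\tfrac12 R^T (\\gamma^2 A)^{-1} R

is found by Newton-Raphson on ``(beta, R)`` jointly, and the marginal
(integrated) partial likelihood is approximated by Laplace's method,

.. math:: \\ell_M(\\gamma^2) = \\ell_p(\\hat\\beta, \\hat R)
          - \\tfrac12 \\log\\det(I + \\gamma^2 A H)

with ``H`` the curvature of the negative partial log-likelihood in the
linear predictor at the mode.  An outer bounded search on
:math:`\\log \\gamma^2` maximizes :math:`\\ell_M`.  Ties are handled with the
Breslow approximation throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .gaussian_mixed import CorrelationModel
from .pedigree import KinshipMatrix

__all__ = [
    "SurvivalData",
    "CoxFrailtyModel",
    "CoxPartial",
    "CoxFrailtyScorer",
    "penalized_partial_loglik",
    "fit_cox_frailty",
    "fit_cox_iid",
]

GAMMA2_BOUNDS = (1e-6, 10.0)


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the last iterate state."""


@dataclasses.dataclass
class SurvivalData:
    """Right-censored times: observed time t = min(T, C), indicator
    delta = I(T <= C), optional covariate matrix."""

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).astype(int).ravel()
        if self.time.size != self.event.size:
            raise ValueError("time and event lengths differ")
        if np.any(self.time <= 0):
            raise ValueError("observed times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.X is not None:
            self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if self.X.shape[0] != self.time.size:
                raise ValueError("covariate rows must match number of subjects")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclasses.dataclass
class CoxFrailtyModel:
    """A fitted survival node.

    ``loglik`` is the Laplace-approximate integrated partial log-likelihood
    for frailty fits (``kind="frailty"``) and the ordinary maximized partial
    log-likelihood for naive fits (``kind="iid"``).  At ``gamma2 = 0`` the
    two coincide.
    """

    beta: np.ndarray
    R: np.ndarray | None
    gamma2: float
    loglik: float
    kind: str
    n: int
    n_events: int
    cols: tuple[int, ...]
    names: tuple[str, ...] | None = None
    converged: bool = True

    @property
    def n_fixed(self) -> int:
        return len(self.cols)

    @property
    def p_eff(self) -> int:
        return self.n_fixed + (1 if self.kind == "frailty" else 0)


class CoxPartial:
    """Breslow partial log-likelihood, gradient and curvature in the linear
    predictor, via cumulative risk-set sums on time-sorted data."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float).ravel()
        event = np.asarray(event).astype(int).ravel()
        if event.sum() < 1:
            raise ValueError("no events: partial likelihood undefined")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.inv_order = np.argsort(self.order, kind="stable")
        ts = time[self.order]
        self.delta_s = event[self.order]
        ev_times = np.unique(ts[self.delta_s == 1])
        # first sorted index at risk for each distinct event time, and
        # event multiplicities d_j
        self.risk_start = np.searchsorted(ts, ev_times, side="left")
        self.d = np.array([
            int(((ts == t) & (self.delta_s == 1)).sum()) for t in ev_times
        ])
        # r_i = number of distinct event times <= t_i (index into cumsums)
        self.rank = np.searchsorted(ev_times, ts, side="right")
        self._rank_min: np.ndarray | None = None  # lazy n x n min(rank_i, rank_j)

    def rank_min(self) -> np.ndarray:
        if self._rank_min is None:
            self._rank_min = np.minimum.outer(self.rank, self.rank)
        return self._rank_min

    def _risk_sums(self, es: np.ndarray) -> np.ndarray:
        revcum = np.cumsum(es[::-1])[::-1]
        return revcum[self.risk_start]

    def loglik(self, eta: np.ndarray) -> float:
        etas = eta[self.order]
        es = np.exp(etas)
        S = self._risk_sums(es)
        return float(etas @ self.delta_s - self.d @ np.log(S))

    def grad(self, eta: np.ndarray) -> np.ndarray:
        etas = eta[self.order]
        es = np.exp(etas)
        S = self._risk_sums(es)
        G = np.concatenate(([0.0], np.cumsum(self.d / S)))[self.rank]
        g = self.delta_s - es * G
        return g[self.inv_order]

    # sorted-order kernels (used internally by the frailty scorer) ---------
    def loglik_sorted(self, etas: np.ndarray) -> float:
        es = np.exp(etas)
        S = self._risk_sums(es)
        return float(etas @ self.delta_s - self.d @ np.log(S))

    def grad_sorted(self, etas: np.ndarray) -> np.ndarray:
        es = np.exp(etas)
        S = self._risk_sums(es)
        G = np.concatenate(([0.0], np.cumsum(self.d / S)))[self.rank]
        return self.delta_s - es * G

    def neg_hessian_sorted(self, etas: np.ndarray) -> np.ndarray:
        es = np.exp(etas)
        S = self._risk_sums(es)
        Gcum = np.concatenate(([0.0], np.cumsum(self.d / S)))
        Ccum = np.concatenate(([0.0], np.cumsum(self.d / S**2)))
        H = np.outer(es, -es)
        H *= Ccum[self.rank_min()]
        H[np.diag_indices_from(H)] += es * Gcum[self.rank]
        return H

    def neg_hessian(self, eta: np.ndarray) -> np.ndarray:
        """Dense curvature matrix H = -d^2 loglik / d eta^2 (PSD)."""
        H = self.neg_hessian_sorted(eta[self.order])
        return H[np.ix_(self.inv_order, self.inv_order)]

    def beta_derivatives(self, X: np.ndarray, beta: np.ndarray):
        """(loglik, gradient, negative Hessian) in beta for the naive Cox
        model, via reverse cumulative sums (no n x n matrix)."""
        eta = X @ beta
        etas = eta[self.order]
        Xs = X[self.order]
        es = np.exp(etas)
        wX = es[:, None] * Xs
        wXX = np.einsum("i,ij,ik->ijk", es, Xs, Xs)
        S = self._risk_sums(es)
        S1 = np.cumsum(wX[::-1], axis=0)[::-1][self.risk_start]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1][self.risk_start]
        ll = float(etas @ self.delta_s - self.d @ np.log(S))
        xbar = S1 / S[:, None]
        grad = (self.delta_s[:, None] * Xs).sum(axis=0) - self.d @ xbar
        info = np.einsum("j,jkl->kl", self.d / S, S2) - np.einsum(
            "j,jk,jl->kl", self.d, xbar, xbar
        )
        return ll, grad, info


def _structure_dense(corr_or_A, n: int):
    """Normalize the structure argument to (A dense, block list)."""
    if isinstance(corr_or_A, CorrelationModel):
        if corr_or_A.kind == "iid":
            blocks = [(np.arange(corr_or_A.n), np.eye(corr_or_A.n))]
        else:
            blocks = [(idx, A) for idx, A in corr_or_A.structure_blocks()]
    elif isinstance(corr_or_A, KinshipMatrix):
        blocks = [(np.arange(sl.start, sl.stop), b)
                  for sl, b in zip(corr_or_A.block_slices, corr_or_A.blocks)]
    else:
        A = np.asarray(corr_or_A, dtype=float)
        blocks = [(np.arange(A.shape[0]), A)]
    total = sum(idx.size for idx, _ in blocks)
    if total != n:
        raise ValueError("structure matrix size does not match data")
    return blocks


def penalized_partial_loglik(data: SurvivalData, beta: np.ndarray, R: np.ndarray,
                             gamma2: float, A) -> float:
    """Breslow partial log-likelihood at linear predictor ``X beta + R``
    minus the Gaussian penalty ``R^T (gamma2 A)^{-1} R / 2``.

    A ridge of 1e-8 is added to any singular structure block.
    """
    if gamma2 <= 0:
        raise ValueError("gamma2 must be positive")
    beta = np.asarray(beta, dtype=float).ravel()
    R = np.asarray(R, dtype=float).ravel()
    partial = CoxPartial(data.time, data.event)
    eta = R.copy()
    if beta.size:
        eta = eta + data.X @ beta
    pen = 0.0
    for idx, Ab in _structure_dense(A, data.n):
        r = R[idx]
        try:
            sol = np.linalg.solve(Ab, r)
        except np.linalg.LinAlgError:
            sol = np.linalg.solve(Ab + 1e-8 * np.eye(Ab.shape[0]), r)
        pen += float(r @ sol)
    return partial.loglik(eta) - 0.5 * pen / gamma2


class CoxFrailtyScorer:
    """Repeated frailty and naive Cox fits over sub-designs of one dataset.

    Precomputes the time-sorted partial-likelihood structure and the
    blockwise inverse and log-determinant of ``A``; fits are cached by
    column subset, and the outer variance search warm-starts its inner
    Newton iterations from the previous mode.
    """

    def __init__(self, data: SurvivalData, corr, names: Sequence[str] | None = None,
                 gamma2_bounds: tuple[float, float] = GAMMA2_BOUNDS,
                 gamma2_tol: float = 1e-4, ridge: float = 1e-8):
        self.data = data
        self.partial = CoxPartial(data.time, data.event)
        self.n = data.n
        self.n_events = data.n_events
        self.X_full = data.X if data.X is not None else np.empty((self.n, 0))
        self.p_full = self.X_full.shape[1]
        self.names = tuple(names) if names is not None else None
        self.gamma2_bounds = gamma2_bounds
        self.gamma2_tol = gamma2_tol
        self.blocks = _structure_dense(corr, self.n)
        self._Xs = self.X_full[self.partial.order]  # time-sorted design
        self._ridge = ridge
        self._Ainv: np.ndarray | None = None
        self._logdet_A = 0.0
        self._cache: dict[tuple, CoxFrailtyModel] = {}
        self._warm: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    # -- penalty helpers -------------------------------------------------
    def _structure_inverse(self) -> np.ndarray:
        """Dense A^{-1} in time-sorted coordinates (lazy: frailty fits only)."""
        if self._Ainv is None:
            inv_order = self.partial.inv_order
            self._Ainv = np.zeros((self.n, self.n))
            self._logdet_A = 0.0
            for idx, Ab in self.blocks:
                sign, logdet = np.linalg.slogdet(Ab)
                if sign <= 0 or logdet < np.log(1e-10) * Ab.shape[0]:
                    Ab = Ab + self._ridge * np.eye(Ab.shape[0])
                    sign, logdet = np.linalg.slogdet(Ab)
                pos = inv_order[idx]
                self._Ainv[np.ix_(pos, pos)] = np.linalg.inv(Ab)
                self._logdet_A += float(logdet)
        return self._Ainv

    def _penalty_matrix(self, gamma2: float) -> np.ndarray:
        """(gamma2 A)^{-1} in sorted coordinates."""
        return self._structure_inverse() / gamma2

    # -- inner PPL Newton (sorted coordinates) ---------------------------
    def _inner(self, Xc: np.ndarray, gamma2: float, beta0, R0, max_iter: int = 50,
               tol: float = 1e-9):
        """Newton-Raphson on (beta, R) of the penalized partial likelihood.

        Exits on small *predicted* Newton improvement so the curvature
        matrix returned is current at the mode.
        """
        p = Xc.shape[1]
        beta = beta0.copy()
        R = R0.copy()
        P = self._penalty_matrix(gamma2)
        partial = self.partial

        def pll(beta, R):
            eta = R + (Xc @ beta if p else 0.0)
            return partial.loglik_sorted(eta) - 0.5 * float(R @ (P @ R)), eta

        cur, eta = pll(beta, R)
        for _ in range(max_iter):
            g_eta = partial.grad_sorted(eta)
            H = partial.neg_hessian_sorted(eta)
            grad = np.concatenate([Xc.T @ g_eta, g_eta - P @ R])
            HP = H + P
            J = np.empty((p + self.n, p + self.n))
            HX = H @ Xc if p else np.empty((self.n, 0))
            J[:p, :p] = Xc.T @ HX + 1e-10 * np.eye(p)
            J[:p, p:] = HX.T
            J[p:, :p] = HX
            J[p:, p:] = HP
            try:
                c, low = cho_factor(J, lower=True)
                step = cho_solve((c, low), grad)
            except np.linalg.LinAlgError:
                J[np.diag_indices_from(J)] += 1e-6
                c, low = cho_factor(J, lower=True)
                step = cho_solve((c, low), grad)
            if 0.5 * float(grad @ step) < tol * (1.0 + abs(cur)):
                return beta, R, cur, HP  # converged; H is current
            t = 1.0
            for _ in range(30):
                nb = beta + t * step[:p]
                nR = R + t * step[p:]
                new, neta = pll(nb, nR)
                if new >= cur - 1e-12:
                    break
                t *= 0.5
            else:
                raise ConvergenceError(
                    f"penalized-likelihood step failed at gamma2={gamma2:.3g}"
                )
            beta, R, cur, eta = nb, nR, new, neta
        raise ConvergenceError(
            f"inner Newton did not converge at gamma2={gamma2:.3g} "
            f"(last penalized loglik {cur:.6g})"
        )

    def _laplace(self, cols: tuple[int, ...], gamma2: float):
        Xc = self._Xs[:, cols] if cols else np.empty((self.n, 0))
        key = cols
        beta0, R0 = self._warm.get(key, (np.zeros(len(cols)), np.zeros(self.n)))
        beta, R, pen_ll, HP = self._inner(Xc, gamma2, beta0, R0)
        self._warm[key] = (beta, R)
        try:
            chol = np.linalg.cholesky(HP)
        except np.linalg.LinAlgError:
            raise ConvergenceError("non-positive curvature at penalized mode") from None
        logdet_HP = 2.0 * float(np.log(np.diag(chol)).sum())
        logdet_P = -self.n * np.log(gamma2) - self._logdet_A
        ll_m = pen_ll - 0.5 * (logdet_HP - logdet_P)
        return ll_m, beta, R

    # -- public fits -----------------------------------------------------
    def fit(self, cols: Sequence[int] | None = None) -> CoxFrailtyModel:
        """Frailty fit: Laplace-approximate integrated partial likelihood
        maximized over gamma2 on a log scale."""
        cols = tuple(range(self.p_full)) if cols is None else tuple(cols)
        key = ("frailty", cols)
        if key in self._cache:
            return self._cache[key]
        lo, hi = np.log(self.gamma2_bounds)

        def obj(u: float) -> float:
            return -self._laplace(cols, float(np.exp(u)))[0]

        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": self.gamma2_tol})
        gamma2 = float(np.exp(res.x))
        ll, beta, R = self._laplace(cols, gamma2)
        # guard nesting monotonicity against outer-search tolerance: a model
        # must do at least as well as any cached sub-model did at its own
        # variance optimum, so try those gamma2 values too
        sub_g2 = {
            round(m.gamma2, 12)
            for (kind, sub), m in self._cache.items()
            if kind == "frailty" and set(sub) < set(cols)
        }
        for g2 in sub_g2 - {round(gamma2, 12)}:
            ll2, beta2, R2 = self._laplace(cols, g2)
            if ll2 > ll:
                ll, beta, R, gamma2 = ll2, beta2, R2, g2
        model = CoxFrailtyModel(
            beta=beta, R=R[self.partial.inv_order], gamma2=gamma2, loglik=ll, kind="frailty",
            n=self.n, n_events=self.n_events, cols=cols,
            names=self._colnames(cols),
        )
        self._cache[key] = model
        return model

    def fit_iid(self, cols: Sequence[int] | None = None, max_iter: int = 50,
                tol: float = 1e-10) -> CoxFrailtyModel:
        """Standard Cox partial-likelihood fit (no frailty)."""
        cols = tuple(range(self.p_full)) if cols is None else tuple(cols)
        key = ("iid", cols)
        if key in self._cache:
            return self._cache[key]
        Xc = self.X_full[:, cols]
        p = len(cols)
        beta = np.zeros(p)
        if p == 0:
            ll = self.partial.loglik(np.zeros(self.n))
        else:
            ll, grad, info = self.partial.beta_derivatives(Xc, beta)
            for _ in range(max_iter):
                step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
                t = 1.0
                for _ in range(30):
                    nb = beta + t * step
                    nll, ngrad, ninfo = self.partial.beta_derivatives(Xc, nb)
                    if nll >= ll - 1e-12:
                        break
                    t *= 0.5
                improved = nll - ll
                beta, ll, grad, info = nb, nll, ngrad, ninfo
                if improved < tol * (1.0 + abs(ll)):
                    break
            else:
                raise ConvergenceError("Cox Newton-Raphson did not converge")
        model = CoxFrailtyModel(
            beta=beta, R=None, gamma2=0.0, loglik=ll, kind="iid",
            n=self.n, n_events=self.n_events, cols=cols,
            names=self._colnames(cols),
        )
        self._cache[key] = model
        return model

    def _colnames(self, cols):
        return None if self.names is None else tuple(self.names[c] for c in cols)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_cox_frailty(data: SurvivalData, A, gamma2_tol: float = 1e-4,
                    gamma2_bounds: tuple[float, float] = GAMMA2_BOUNDS) -> CoxFrailtyModel:
    """Fit the Cox model with correlated log-normal frailty ``R ~ N(0, gamma2 A)``."""
    if data.n_events < 1:
        raise ValueError("need at least one event")
    scorer = CoxFrailtyScorer(data, A, gamma2_tol=gamma2_tol,
                              gamma2_bounds=gamma2_bounds)
    return scorer.fit()


def fit_cox_iid(data: SurvivalData) -> CoxFrailtyModel:
    """Standard Cox proportional-hazards fit ignoring any correlation."""
    if data.n_events < 1:
        raise ValueError("need at least one event")
    scorer = CoxFrailtyScorer(data, np.eye(data.n))
    return scorer.fit_iid()
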