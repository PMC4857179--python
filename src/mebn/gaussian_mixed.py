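"""Gaussian node models with correlated random effects.

A continuous node with parent design matrix ``X`` is modelled as

.. math:: y = X\\beta + \\alpha + e, \\qquad
          \\alpha \\sim N(0, \\gamma^2 A), \\quad e \\sim N(0, \\sigma^2 I)

so that :math:`V(y|X) = \\gamma^2 A + \\sigma^2 I`, where ``A`` is a known
block-diagonal structure matrix: the additive relationship matrix ``2K`` for
family data, or a block of ones (random intercept) for exchangeable repeated
measures, or an AR(1) correlation block.  The integrated likelihood (random
effects marginalized out) is available in closed form and is maximized by a
1-D search over the heritability :math:`h^2 = \\gamma^2/(\\gamma^2+\\sigma^2)`
after an eigen-rotation that diagonalizes every family block; the total
variance profiles out in closed form.

:class:`GaussianMixedScorer` caches the rotation and per-eigenvalue-group
Gram matrices of a full candidate design so that the forward search can fit
hundreds of nested sub-models at negligible marginal cost.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .pedigree import KinshipMatrix

__all__ = [
    "CorrelationModel",
    "GaussianMixedModel",
    "GaussianMixedScorer",
    "integrated_loglik_gaussian",
    "fit_gaussian_mixed",
    "fit_gaussian_iid",
]

_H2_MAX = 1.0 - 1e-6


class CorrelationModel:
    """Known correlation structure: block-diagonal ``A`` plus its rotation.

    ``blocks`` is a list of ``(row_indices, U_f, s_f, A_f)`` where
    ``A_f = U_f diag(s_f) U_f^T`` is one cluster's structure matrix and
    ``row_indices`` maps the block into data rows.
    """

    def __init__(self, kind: str, n: int, blocks, labels=None, rho: float | None = None):
        self.kind = kind
        self.n = n
        self.blocks = blocks
        self.labels = labels
        self.rho = rho
        self.s_full = np.concatenate([s for _, _, s, _ in blocks]) if blocks else np.ones(n)

    # -- constructors ----------------------------------------------------
    @classmethod
    def iid(cls, n: int) -> "CorrelationModel":
        # no blocks: the rotation is the identity and all eigenvalues are 1
        return cls("iid", n, [])

    @classmethod
    def from_kinship(cls, K: KinshipMatrix) -> "CorrelationModel":
        blocks = []
        for sl, (U, s), A in zip(K.block_slices, K.eigens(), K.blocks):
            blocks.append((np.arange(sl.start, sl.stop), U, s, A))
        return cls("kinship", K.n, blocks, labels=np.asarray(K.family))

    @classmethod
    def exchangeable(cls, clusters: Sequence) -> "CorrelationModel":
        """Random-intercept structure: A is a block of ones per cluster, so the
        within-cluster correlation of the marginal model equals h^2."""
        return cls._from_structure("exchangeable", clusters, lambda m: np.ones((m, m)))

    @classmethod
    def ar1(cls, clusters: Sequence, rho: float) -> "CorrelationModel":
        if not -1 < rho < 1:
            raise ValueError("AR(1) correlation must be in (-1, 1)")

        def block(m: int) -> np.ndarray:
            idx = np.arange(m)
            return rho ** np.abs(idx[:, None] - idx[None, :])

        return cls._from_structure("ar1", clusters, block, rho=rho)

    @classmethod
    def _from_structure(cls, kind, clusters, block_fn, rho=None) -> "CorrelationModel":
        labels = np.asarray(clusters)
        n = labels.size
        blocks = []
        _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
        order = np.argsort(first, kind="stable")  # clusters in order of appearance
        cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for c in order:
            idx = np.flatnonzero(inverse == c)
            m = idx.size
            if m not in cache:
                A = block_fn(m)
                s, U = np.linalg.eigh(A)
                cache[m] = (U, s, A)
            U, s, A = cache[m]
            blocks.append((idx, U, s, A))
        return cls(kind, n, blocks, labels=labels, rho=rho)

    # -- operations ------------------------------------------------------
    @property
    def n_clusters(self) -> int:
        return len(self.blocks) if self.kind != "iid" else self.n

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """Apply the blockwise transpose-eigenvector rotation to rows of M."""
        M = np.asarray(M, dtype=float)
        if self.kind == "iid":
            return M.copy()
        out = np.empty_like(M)
        for idx, U, _, _ in self.blocks:
            out[idx] = U.T @ M[idx]
        return out

    def structure_blocks(self):
        """Yield ``(row_indices, A_f)`` pairs."""
        for idx, _, _, A in self.blocks:
            yield idx, A


@dataclasses.dataclass
class GaussianMixedModel:
    """A fitted Gaussian node: fixed effects, variance components, and the
    integrated log-likelihood."""

    beta: np.ndarray
    gamma2: float
    sigma2: float
    loglik: float
    n: int
    cols: tuple[int, ...]
    kind: str  # "mixed" or "iid"
    corr_kind: str = "iid"
    names: tuple[str, ...] | None = None
    degenerate: bool = False

    @property
    def h2(self) -> float:
        tot = self.gamma2 + self.sigma2
        return 0.0 if tot == 0 else self.gamma2 / tot

    @property
    def n_fixed(self) -> int:
        """Number of fixed-effect coefficients (including intercept)."""
        return len(self.cols)

    @property
    def p_eff(self) -> int:
        """Parameter count: fixed effects plus variance components."""
        return self.n_fixed + (2 if self.kind == "mixed" else 1)


class GaussianMixedScorer:
    """Repeated ML fits of sub-designs of one (y, X, correlation) triple.

    Rotates ``y`` and the full candidate design once, groups rotated rows by
    structure eigenvalue, and stores per-group Gram matrices; every profile
    evaluation for any column subset then reduces to a handful of small
    matrix operations independent of n.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, corr: CorrelationModel,
                 names: Sequence[str] | None = None):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size or corr.n != y.size:
            raise ValueError("y, X and correlation model have inconsistent shapes")
        self.n = y.size
        self.p_full = X.shape[1]
        self.corr = corr
        self.names = tuple(names) if names is not None else None
        yr = corr.rotate(y[:, None]).ravel()
        Xr = corr.rotate(X)
        s = corr.s_full
        keys = np.round(s, 12)
        uniq, inverse = np.unique(keys, return_inverse=True)
        self.s_groups = uniq
        self.m_groups = np.bincount(inverse).astype(float)
        G, b, c = [], [], []
        for g in range(uniq.size):
            mask = inverse == g
            Xg = Xr[mask]
            yg = yr[mask]
            G.append(Xg.T @ Xg)
            b.append(Xg.T @ yg)
            c.append(float(yg @ yg))
        self.G = np.stack(G)          # (ngroup, p, p)
        self.b = np.stack(b)          # (ngroup, p)
        self.c = np.asarray(c)        # (ngroup,)
        self._cache: dict[tuple, GaussianMixedModel] = {}

    # -- internals -------------------------------------------------------
    def _suff(self, cols: tuple[int, ...]):
        ix = np.asarray(cols)
        return self.G[:, ix[:, None], ix[None, :]], self.b[:, ix]

    @staticmethod
    def _solve_normal(XtWX, XtWy):
        # Cholesky: fails loudly on a rank-deficient (PSD-singular) design
        try:
            c = np.linalg.cholesky(XtWX)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular rotated design: candidate columns are collinear"
            ) from None
        z = np.linalg.solve(c, XtWy)
        return np.linalg.solve(c.T, z)

    def _gls(self, w, G, b):
        """Weighted normal equations from grouped sufficient statistics."""
        XtWX = np.tensordot(w, G, axes=1)
        XtWy = w @ b
        beta = self._solve_normal(XtWX, XtWy)
        ytWy = w @ self.c
        rss = ytWy - beta @ XtWy
        return beta, max(rss, 0.0), XtWy

    def _profile(self, h2: float, G, b):
        """Profile out beta and the total variance at fixed h^2; return
        (negative log-likelihood, beta, sigma_tot^2)."""
        v = (1.0 - h2) + h2 * self.s_groups
        wg = 1.0 / v
        XtWX = np.tensordot(wg, G, axes=1)
        XtWy = wg @ b
        beta = self._solve_normal(XtWX, XtWy)
        rss = max(float(wg @ self.c - beta @ XtWy), 0.0)
        n = self.n
        logdet = float(self.m_groups @ np.log(v))
        if rss <= 0.0:
            return -np.inf, beta, 0.0, logdet
        s2tot = rss / n
        nll = 0.5 * (n * np.log(2.0 * np.pi * s2tot) + n + logdet)
        return nll, beta, s2tot, logdet

    # -- public fits -----------------------------------------------------
    def fit(self, cols: Sequence[int] | None = None) -> GaussianMixedModel:
        """ML fit of the mixed model on the given design columns."""
        cols = tuple(range(self.p_full)) if cols is None else tuple(cols)
        key = ("mixed", cols)
        if key in self._cache:
            return self._cache[key]
        if self.corr.kind == "iid":
            model = self.fit_iid(cols)
            model = dataclasses.replace(model, kind="mixed", gamma2=0.0)
            self._cache[key] = model
            return model
        G, b = self._suff(cols)

        def obj(h2: float) -> float:
            return self._profile(h2, G, b)[0]

        res = minimize_scalar(obj, bounds=(0.0, _H2_MAX), method="bounded",
                              options={"xatol": 1e-8})
        h2 = float(res.x)
        if obj(0.0) <= res.fun:  # boundary: no cluster variance
            h2 = 0.0
        nll, beta, s2tot, _ = self._profile(h2, G, b)
        model = GaussianMixedModel(
            beta=beta,
            gamma2=h2 * s2tot,
            sigma2=(1.0 - h2) * s2tot,
            loglik=-nll,
            n=self.n,
            cols=cols,
            kind="mixed",
            corr_kind=self.corr.kind,
            names=self._colnames(cols),
            degenerate=not np.isfinite(nll),
        )
        self._cache[key] = model
        return model

    def fit_iid(self, cols: Sequence[int] | None = None) -> GaussianMixedModel:
        """Ordinary least squares with ML error variance (naive comparator)."""
        cols = tuple(range(self.p_full)) if cols is None else tuple(cols)
        key = ("iid", cols)
        if key in self._cache:
            return self._cache[key]
        G, b = self._suff(cols)
        w = np.ones_like(self.s_groups)
        beta, rss, _ = self._gls(w, G, b)
        n = self.n
        s2 = rss / n
        if s2 > 0:
            ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + n)
            degenerate = False
        else:
            ll = np.inf
            degenerate = True
        model = GaussianMixedModel(
            beta=beta, gamma2=0.0, sigma2=s2, loglik=ll, n=n, cols=cols,
            kind="iid", corr_kind=self.corr.kind, names=self._colnames(cols),
            degenerate=degenerate,
        )
        self._cache[key] = model
        return model

    def loglik_at(self, cols: Sequence[int] | None, gamma2: float, sigma2: float) -> float:
        """Exact integrated log-likelihood at fixed variance components, with
        beta profiled by GLS."""
        if gamma2 < 0 or sigma2 <= 0:
            raise ValueError("require gamma2 >= 0 and sigma2 > 0")
        cols = tuple(range(self.p_full)) if cols is None else tuple(cols)
        G, b = self._suff(cols)
        v = sigma2 + gamma2 * self.s_groups
        wg = 1.0 / v
        beta, rss_w, _ = self._gls(wg, G, b)
        logdet = float(self.m_groups @ np.log(v))
        return -0.5 * (self.n * np.log(2.0 * np.pi) + logdet + rss_w)

    def _colnames(self, cols):
        return None if self.names is None else tuple(self.names[c] for c in cols)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def integrated_loglik_gaussian(y, X, corr: CorrelationModel, gamma2: float,
                               sigma2: float) -> float:
    """Integrated Gaussian log-likelihood at fixed variance components.

    Equals the multivariate-normal log-density of ``y`` at the GLS estimate
    of the fixed effects with covariance ``gamma2 * A + sigma2 * I``,
    evaluated per cluster block through the eigen-rotation.
    """
    return GaussianMixedScorer(y, X, corr).loglik_at(None, gamma2, sigma2)


def fit_gaussian_mixed(y, X, corr: CorrelationModel,
                       ar1_grid: Sequence[float] | None = None) -> GaussianMixedModel:
    """ML fit of the Gaussian mixed model.

    For AR(1) repeated measures the autocorrelation is profiled on a coarse
    grid and refined by bounded scalar minimization; other structures need
    only the 1-D heritability search.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    if corr.kind == "ar1" and corr.rho is None:
        raise ValueError("AR(1) structure requires a correlation parameter")
    if corr.kind == "ar1" and ar1_grid is not None:
        labels = corr.labels

        def best_at(rho: float) -> GaussianMixedModel:
            return GaussianMixedScorer(y, X, CorrelationModel.ar1(labels, rho)).fit()

        fits = {rho: best_at(rho) for rho in ar1_grid}
        rho0 = max(fits, key=lambda r: fits[r].loglik)
        lo = max(min(ar1_grid), rho0 - 0.1)
        hi = min(max(ar1_grid), rho0 + 0.1)
        res = minimize_scalar(lambda r: -best_at(r).loglik, bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-6})
        return best_at(float(res.x))
    return GaussianMixedScorer(y, X, corr).fit()


def fit_gaussian_iid(y, X) -> GaussianMixedModel:
    """Ordinary (naive) Gaussian fit ignoring any correlation."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if y.size <= X.shape[1]:
        raise ValueError("need n > p observations")
    return GaussianMixedScorer(y, X, CorrelationModel.iid(y.size)).fit_iid()
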