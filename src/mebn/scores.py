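"""Model-selection metrics for node models fitted to correlated data.

Nine metrics are supported.  Six use the integrated likelihood (random
effects marginalized out): ``BIC_M`` (full sample size), ``BIC_J`` (Jones'
effective sample size), ``BIC_Y`` (Yang's effective sample size), ``BIC_C``
(number of clusters, the most liberal correction), ``AIC_M`` and ``LRT_M``.
Three are the naive counterparts computed from the IID likelihood that
ignores correlation: ``BIC_F``, ``AIC_F`` and ``LRT_F``.

All information criteria follow the "lower is better" convention
``-2 loglik + penalty``.  For survival nodes the BIC sample size is the
number of events, the usual convention for Cox models.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .gaussian_mixed import CorrelationModel
from .pedigree import KinshipMatrix

__all__ = [
    "METRICS",
    "MetricInfo",
    "ScoreConfig",
    "effective_n_jones",
    "effective_n_yang",
    "effective_n_cluster",
    "score_model",
    "lrt_pvalue",
]


@dataclasses.dataclass(frozen=True)
class MetricInfo:
    label: str
    integrated: bool          # integrated vs naive (IID) likelihood
    rule: str                 # "ic" (score improvement) or "lrt" (p < alpha)
    penalty: str | None       # "bic", "aic" or None for LRT
    ne_rule: str | None       # "n", "jones", "yang", "cluster"


METRICS: dict[str, MetricInfo] = {
    m.label: m
    for m in [
        MetricInfo("BIC_M", True, "ic", "bic", "n"),
        MetricInfo("BIC_J", True, "ic", "bic", "jones"),
        MetricInfo("BIC_Y", True, "ic", "bic", "yang"),
        MetricInfo("BIC_C", True, "ic", "bic", "cluster"),
        MetricInfo("AIC_M", True, "ic", "aic", None),
        MetricInfo("LRT_M", True, "lrt", None, None),
        MetricInfo("BIC_F", False, "ic", "bic", "n"),
        MetricInfo("AIC_F", False, "ic", "aic", None),
        MetricInfo("LRT_F", False, "lrt", None, None),
    ]
}


@dataclasses.dataclass(frozen=True)
class ScoreConfig:
    """Which metric governs selection, and at what level.

    ``alpha`` applies to the LRT metrics; with ``bonferroni=True`` it is
    divided by the number of level-1 candidate parents of the node.
    """

    metric: str = "LRT_M"
    alpha: float = 0.05
    bonferroni: bool = False

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; valid: {sorted(METRICS)}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def info(self) -> MetricInfo:
        return METRICS[self.metric]


# ---------------------------------------------------------------------------
# effective sample sizes
# ---------------------------------------------------------------------------

def _correlation_blocks(corr: CorrelationModel, gamma2: float, sigma2: float):
    """Implied correlation matrix of V = gamma2*A + sigma2*I, per cluster."""
    for _, A in corr.structure_blocks():
        V = gamma2 * A + sigma2 * np.eye(A.shape[0])
        d = np.sqrt(np.diag(V))
        yield V / np.outer(d, d)


def effective_n_jones(corr: CorrelationModel, gamma2: float, sigma2: float) -> float:
    """Jones' effective sample size ``n_e = 1^T C^{-1} 1``.

    ``C`` is the correlation matrix implied by ``V = gamma2*A + sigma2*I``;
    block-diagonality makes the quadratic form a sum over clusters.  For one
    exchangeable cluster of size m with correlation rho this reduces to the
    closed form ``m / (1 + (m-1) rho)``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if gamma2 == 0 or corr.kind == "iid":
        return float(corr.n)
    one_sum = 0.0
    for C in _correlation_blocks(corr, gamma2, sigma2):
        ones = np.ones(C.shape[0])
        try:
            one_sum += float(ones @ np.linalg.solve(C, ones))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular implied correlation block") from None
    return one_sum


def effective_n_yang(kinship: KinshipMatrix | CorrelationModel, h2: float) -> float:
    """Family-based effective sample size ``n_e = sum_f n_f^2 / (1^T C_f 1)``.

    ``C_f`` is the family's implied correlation matrix at heritability
    ``h2``.  By Cauchy-Schwarz this never exceeds Jones' correction, and it
    reduces to the same exchangeable closed form; it is bounded below by the
    number of families.
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    corr = kinship if isinstance(kinship, CorrelationModel) else CorrelationModel.from_kinship(kinship)
    if h2 == 0 or corr.kind == "iid":
        return float(corr.n)
    total = 0.0
    for C in _correlation_blocks(corr, h2, 1.0 - h2):
        m = C.shape[0]
        total += m * m / float(C.sum())
    return total


def effective_n_cluster(corr: CorrelationModel) -> float:
    """The most liberal correction: one cluster counts as one sample unit."""
    return float(corr.n_clusters)


def effective_n(corr: CorrelationModel, rule: str, gamma2: float = 0.0,
                sigma2: float = 1.0) -> float:
    """Dispatch an effective-sample-size rule label."""
    if rule == "n":
        return float(corr.n)
    if rule == "jones":
        return effective_n_jones(corr, gamma2, sigma2)
    if rule == "yang":
        tot = gamma2 + sigma2
        return effective_n_yang(corr, gamma2 / tot if tot > 0 else 0.0)
    if rule == "cluster":
        return effective_n_cluster(corr)
    raise ValueError(f"unknown effective-n rule {rule!r}")


# ---------------------------------------------------------------------------
# scoring and testing
# ---------------------------------------------------------------------------

def score_model(model, cfg: ScoreConfig, n_e: float | None = None) -> float:
    """Information-criterion value of a fitted node model (lower is better).

    BIC variants are ``-2 loglik + p_eff * log(n_e)``; AIC is
    ``-2 loglik + 2 p_eff``.  The likelihood must already match the metric
    (integrated for M/J/Y/C metrics, IID for F metrics).
    """
    info = cfg.info
    if info.penalty is None:
        raise ValueError(f"{cfg.metric} is a test, not an information criterion")
    if info.penalty == "aic":
        return -2.0 * model.loglik + 2.0 * model.p_eff
    if n_e is None:
        raise ValueError(f"{cfg.metric} requires an effective sample size")
    return -2.0 * model.loglik + model.p_eff * np.log(n_e)


def lrt_pvalue(full, reduced, tol: float | None = None) -> float:
    """Likelihood-ratio p-value for nested fixed effects.

    The statistic is ``2 (loglik_full - loglik_reduced)`` referred to a
    chi-square with df equal to the difference in fixed-effect counts; the
    variance components are re-estimated under both hypotheses and are not
    counted (same parameter space under both).

    Small negative statistics within ``tol`` are clipped to zero (p = 1):
    exact likelihoods incur only round-off, but Laplace-approximate ones
    (survival nodes) are non-monotone in nesting at the ~1e-3 level because
    the curvature correction moves with the mode.  Beyond ``tol`` a negative
    statistic indicates an optimizer failure and raises.
    """
    df = full.n_fixed - reduced.n_fixed
    if df <= 0:
        raise ValueError("full model must have more fixed effects than reduced")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if tol is None:
        tol = max(1e-8 * abs(reduced.loglik), 1e-6)
    if stat < -tol:
        raise FloatingPointError(
            f"negative LRT statistic {stat:.3g}: optimizer failure in nested fits"
        )
    return float(stats.chi2.sf(max(stat, 0.0), df))
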