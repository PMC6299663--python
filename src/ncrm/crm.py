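"""Classical one-parameter CRM comparators (empiric/power and logistic).

The empiric (power) model takes ``p_k(beta) = p_{0k}^{exp(beta)}`` with a
skeleton ``p_{01} < ... < p_{0K}`` of prior toxicity guesses; the
one-parameter logistic model takes ``p_k(beta) = expit(a0 + beta * x_k)`` on
standardised doses ``x_k = logit(p_{0k}) - a0`` so that ``beta = 1`` recovers
the skeleton.  The parameter has a normal prior (mean 0, variance 1.34 by the
dfcrm convention) and its posterior mean is computed by deterministic
quadrature; the next cohort is assigned the dose whose model toxicity at the
posterior-mean parameter is closest to the target.

Skeletons are generated by the indifference-interval construction of Lee &
Cheung for the empiric model: the entry at the prior MTD position equals the
target, and consecutive entries are spaced so each dose owns an indifference
interval of half-width delta around the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = ["Skeleton", "skeleton_getprior", "ParametricCRM", "CRMResults",
           "crm_dose_toxicity", "crm_posterior_mean_beta", "crm_next_dose"]


@dataclass(frozen=True)
class Skeleton:
    """Prior toxicity guesses with their indifference half-width and anchor."""

    p0: np.ndarray
    delta: float
    nu: int  # 1-based prior MTD position

    def __post_init__(self):
        p0 = np.asarray(self.p0, dtype=float)
        if not (np.all(p0 > 0) and np.all(p0 < 1) and np.all(np.diff(p0) > 0)):
            raise ValueError("skeleton must be strictly increasing inside (0, 1)")
        object.__setattr__(self, "p0", p0)

    @property
    def K(self) -> int:
        return self.p0.size


def skeleton_getprior(delta: float, theta: float, nu: int, K: int) -> Skeleton:
    """Indifference-interval skeleton for the empiric model.

    Anchors ``p0[nu] = theta`` and extends outward with the recursion
    ``log p0[k+1] = log p0[k] * log(theta+delta) / log(theta-delta)`` going up
    (its reciprocal going down), so that the power-model parameter mapping one
    dose to the edge of the indifference interval maps its neighbour to the
    target.
    """
    if not 0 < delta < min(theta, 1 - theta):
        raise ValueError("delta must satisfy 0 < delta < min(theta, 1-theta)")
    if not 1 <= nu <= K:
        raise ValueError("nu must lie in 1..K")
    ratio = np.log(theta + delta) / np.log(theta - delta)  # in (0, 1)
    logp = np.empty(K)
    logp[nu - 1] = np.log(theta)
    for k in range(nu, K):
        logp[k] = logp[k - 1] * ratio
    for k in range(nu - 2, -1, -1):
        logp[k] = logp[k + 1] / ratio
    p0 = np.exp(logp)
    if not (np.all(p0 > 0) and np.all(p0 < 1)):
        raise ValueError("infeasible delta: skeleton leaves (0, 1)")
    return Skeleton(p0, delta, nu)


def crm_dose_toxicity(model: "ParametricCRM", k: int, beta: float):
    """Model toxicity probability at 1-based dose k for parameter beta."""
    p0k = model.skeleton.p0[k - 1]
    if model.variant == "power":
        return float(p0k ** np.exp(beta))
    x_k = logit(p0k) - model.a0
    return float(expit(model.a0 + beta * x_k))


def _model_probs(model: "ParametricCRM", beta):
    """Vectorised toxicity probabilities, shape (len(beta), K)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p0 = model.skeleton.p0
    if model.variant == "power":
        return p0[None, :] ** np.exp(beta)[:, None]
    x = logit(p0) - model.a0
    return expit(model.a0 + beta[:, None] * x[None, :])


def crm_posterior_mean_beta(model: "ParametricCRM", cohorts) -> float:
    """Posterior mean of beta by deterministic quadrature on [-10, 10].

    ``cohorts`` is a list of ``(dose_index, n, y)`` triples (1-based dose).
    The normal prior has mean 0 and variance ``model.beta_prior_var``; the
    integrand is evaluated on a uniform grid of ``model.n_quad`` nodes and
    integrated by the trapezoid rule in a numerically safe log formulation.
    """
    beta = np.linspace(-10.0, 10.0, model.n_quad)
    loglik = np.zeros_like(beta)
    if cohorts:
        P = _model_probs(model, beta)
        for k, n, y in cohorts:
            p = np.clip(P[:, k - 1], 1e-300, 1 - 1e-16)
            loglik += y * np.log(p) + (n - y) * np.log1p(-p)
    logprior = -0.5 * beta**2 / model.beta_prior_var
    logpost = loglik + logprior
    logpost -= logpost.max()
    w = np.exp(logpost)
    denom = np.trapezoid(w, beta)
    if denom <= 0 or not np.isfinite(denom):
        raise FloatingPointError("vanishing posterior normaliser")
    return float(np.trapezoid(beta * w, beta) / denom)


def crm_next_dose(model: "ParametricCRM", beta_hat: float, theta: float) -> int:
    """1-based dose whose model toxicity at beta_hat is closest to theta."""
    p = _model_probs(model, beta_hat)[0]
    return int(np.argmin(np.abs(p - theta))) + 1


@dataclass(frozen=True)
class ParametricCRM:
    """One-parameter CRM with a power or logistic dose-toxicity model.

    Examples
    --------
    >>> sk = skeleton_getprior(0.05, 0.3, 5, 8)
    >>> crm = ParametricCRM(sk, variant="power")
    >>> res = crm.fit([(1, 3, 0), (2, 3, 1)], theta=0.3)
    >>> res.next_dose  # doctest: +SKIP
    3
    """

    skeleton: Skeleton
    variant: str = "power"
    a0: float = 3.0
    beta_prior_var: float = 1.34
    n_quad: int = 2001

    def __post_init__(self):
        if self.variant not in ("power", "logistic"):
            raise ValueError("variant must be 'power' or 'logistic'")
        if not self.beta_prior_var > 0:
            raise ValueError("beta prior variance must be positive")

    def dose_toxicity(self, k: int, beta: float) -> float:
        return crm_dose_toxicity(self, k, beta)

    def fit(self, cohorts, theta: float) -> "CRMResults":
        """Posterior-mean fit to the accumulated ``(dose, n, y)`` cohorts."""
        beta_hat = crm_posterior_mean_beta(self, list(cohorts))
        return CRMResults(self, float(beta_hat), float(theta), list(cohorts))


@dataclass
class CRMResults:
    """Fitted comparator: posterior-mean parameter and derived quantities."""

    model: ParametricCRM
    beta_hat: float
    theta: float
    cohorts: list = field(default_factory=list)

    @property
    def p_hat(self) -> np.ndarray:
        """Estimated toxicity probabilities at every dose."""
        return _model_probs(self.model, self.beta_hat)[0]

    @property
    def next_dose(self) -> int:
        """Unrestricted model-recommended dose (closest to target)."""
        return crm_next_dose(self.model, self.beta_hat, self.theta)

    def summary(self) -> str:
        import pandas as pd

        df = pd.DataFrame({"dose": np.arange(1, self.model.skeleton.K + 1),
                           "skeleton": np.round(self.model.skeleton.p0, 4),
                           "p_hat": np.round(self.p_hat, 4)})
        head = (f"{self.model.variant} CRM fit: beta_hat={self.beta_hat:.4f}, "
                f"recommended dose {self.next_dose} (theta={self.theta})")
        return head + "\n" + df.to_string(index=False)
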