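"""Dirichlet-process probability model for a monotone dose-toxicity curve.

The dose-toxicity curve ``F`` is treated as an unknown right-continuous
nondecreasing function on the dose axis with range [0, 1], and is given a
Dirichlet-process prior ``F ~ DP(alpha * F0)`` with a normal-CDF base
distribution ``F0(x) = Phi((x - mu) / sigma)``.  For the tried dose levels
``d_1 < ... < d_S`` the induced prior on the toxicity probabilities
``p_k = F(d_k)`` is an ordered-Dirichlet law on the increments

    (p_1 - 0, p_2 - p_1, ..., 1 - p_S) ~ Dirichlet(gamma_1, ..., gamma_{S+1}),

with weights ``gamma_i = alpha * (F0(d_i) - F0(d_{i-1}))`` (conventions
``d_0 = -inf``, ``d_{S+1} = +inf``).  Combined with independent binomial
toxicity counts per dose this yields the unnormalised posterior and the full
conditional densities consumed by the ARMS-within-Gibbs sampler in
:mod:`ncrm.sampler`.

Only kernels (log densities up to additive constants) are exposed; the
Dirichlet normaliser is available separately for completeness but no sampler
path needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

__all__ = [
    "EPS_INCREMENT",
    "DoseGrid",
    "TrialState",
    "BaseDistribution",
    "DPPrior",
    "base_cdf",
    "dirichlet_weights",
    "log_prior_density",
    "log_dirichlet_normalizer",
    "log_likelihood",
    "log_posterior",
    "conditional_logdensity_p",
    "conditional_logdensity_alpha",
    "conditional_logweights_mu_sigma",
    "repair_monotone",
    "DoseToxicityModel",
]

#: minimum increment enforced between consecutive toxicity probabilities
EPS_INCREMENT = 1e-10


@dataclass(frozen=True)
class DoseGrid:
    """Ordered dose labels and the trial's target toxicity probability.

    Parameters
    ----------
    dose_values : array-like
        Strictly increasing dose labels ``d_1 < ... < d_K`` (unitless; trials
        commonly label them 1..K).
    theta : float
        Target toxicity probability, ``0 < theta < 1``.
    """

    dose_values: np.ndarray
    theta: float

    def __post_init__(self):
        d = np.asarray(self.dose_values, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("need at least two dose levels")
        if not np.all(np.diff(d) > 0):
            raise ValueError("dose values must be strictly increasing")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        object.__setattr__(self, "dose_values", d)

    @property
    def K(self) -> int:
        return self.dose_values.size


@dataclass
class TrialState:
    """Accumulated per-dose counts and the cohort-by-cohort assignment log.

    ``n[k]`` patients were treated at dose level ``k+1`` of whom ``y[k]``
    experienced a dose-limiting toxicity.  Tried doses must be contiguous from
    the lowest level; ``S`` is the number of tried doses.
    """

    n: np.ndarray
    y: np.ndarray
    cohort_log: list = field(default_factory=list)

    def __post_init__(self):
        n = np.asarray(self.n, dtype=np.int64)
        y = np.asarray(self.y, dtype=np.int64)
        if n.shape != y.shape or n.ndim != 1:
            raise ValueError("n and y must be 1-d arrays of equal length")
        if np.any(y < 0) or np.any(n < 0) or np.any(y > n):
            raise ValueError("need 0 <= y_k <= n_k at every dose")
        tried = n > 0
        if tried.any():
            last = np.max(np.nonzero(tried)[0])
            if not tried[: last + 1].all():
                raise ValueError("tried doses must be contiguous from d_1")
        self.n, self.y = n, y

    @property
    def S(self) -> int:
        """Number of tried doses (leading non-zero patient counts)."""
        return int(np.count_nonzero(self.n > 0))

    @property
    def n_patients(self) -> int:
        return int(self.n.sum())

    @classmethod
    def empty(cls, K: int) -> "TrialState":
        return cls(np.zeros(K, dtype=np.int64), np.zeros(K, dtype=np.int64))

    def add_cohort(self, dose_level: int, outcomes) -> None:
        """Record one cohort: 1-based dose level and its binary outcomes."""
        outcomes = np.asarray(outcomes, dtype=np.int64)
        self.n[dose_level - 1] += outcomes.size
        self.y[dose_level - 1] += int(outcomes.sum())
        self.cohort_log.append((len(self.cohort_log) + 1, dose_level, outcomes.copy()))
        # re-validate contiguity
        self.__post_init__()


@dataclass(frozen=True)
class BaseDistribution:
    """Normal-CDF base curve ``F0(x) = Phi((x - mu) / sigma)``.

    ``mu`` sits on the dose-label axis; choosing ``Phi((d_k - mu)/sigma) =
    theta`` centres the prior on a guess that dose ``d_k`` is the MTD.
    """

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    def cdf(self, x):
        return norm.cdf((np.asarray(x, dtype=float) - self.mu) / self.sigma)


@dataclass(frozen=True)
class DPPrior:
    """Dirichlet-process prior specification for the dose-toxicity curve.

    Parameters
    ----------
    alpha : float
        DP precision.  Used as a fixed value when ``alpha_fixed`` is True,
        otherwise only as the chain's initial value.
    base : BaseDistribution
        Central base curve ``F0``; its (mu, sigma) serve as grid centres when
        the base parameters are treated as unknown.
    alpha_fixed : bool
        If True the sampler holds (alpha, mu, sigma) at their given values.
    a, b : float
        Shape and rate of the Gamma hyperprior on alpha (mean ``a/b``),
        used when ``alpha_fixed`` is False.
    r : float
        Half-width of the discrete-uniform supports ``[mu0 - r, mu0 + r]`` and
        ``[sigma0 - r, sigma0 + r]`` for the base parameters (the positive part
        of the sigma interval).
    grid_size : int
        Number of equally spaced support points per axis (default 10).
    """

    alpha: float = 5.0
    base: BaseDistribution = field(default_factory=lambda: BaseDistribution(6.0, 2.0))
    alpha_fixed: bool = True
    a: float = 2.0
    b: float = 2.0
    r: float = 1.0
    grid_size: int = 10

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Gamma hyperparameters must be positive")
        if self.r not in (1, 2) and not self.r > 0:
            raise ValueError("half-width r must be positive")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")

    @property
    def mu_grid(self) -> np.ndarray:
        m0 = self.base.mu
        if self.grid_size == 1:
            return np.array([m0])
        return np.linspace(m0 - self.r, m0 + self.r, self.grid_size)

    @property
    def sigma_grid(self) -> np.ndarray:
        """Equally spaced sigma support, non-positive points dropped."""
        s0 = self.base.sigma
        if self.grid_size == 1:
            return np.array([s0])
        g = np.linspace(s0 - self.r, s0 + self.r, self.grid_size)
        return g[g > 0]


def base_cdf(x, base: BaseDistribution):
    """Evaluate the base curve ``F0(x) = Phi((x - mu)/sigma)``."""
    return base.cdf(x)


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    inc = np.diff(np.concatenate(([0.0], p, [1.0])))
    if np.any(inc <= 0):
        raise ValueError("toxicity probabilities must satisfy 0 < p_1 < ... < p_S < 1")
    return p


def repair_monotone(p, eps: float = 1e-4) -> np.ndarray:
    """Force strict monotonicity inside (0, 1) with minimum gap ``eps``.

    Used to sanitise sampler initial values (e.g. a skeleton truncated to the
    tried doses); draws themselves are kept strictly ordered by construction.
    """
    p = np.asarray(p, dtype=float).copy()
    S = p.size
    lo = eps * np.arange(1, S + 1)
    hi = 1.0 - eps * np.arange(S, 0, -1)
    for i in range(S):
        floor = p[i - 1] + eps if i else eps
        p[i] = min(max(p[i], floor, lo[i]), hi[i])
    return p


def dirichlet_weights(prior: DPPrior, grid: DoseGrid, S: int,
                      mu: float | None = None, sigma: float | None = None,
                      alpha: float | None = None) -> np.ndarray:
    """DP-induced Dirichlet weights over the S+1 increments of the curve.

    ``gamma_i = alpha * (F0(d_i) - F0(d_{i-1}))`` for i = 1..S with
    ``F0(d_0) = 0``, and a residual weight ``alpha * (1 - F0(d_S))`` for the
    mass above the highest tried dose.
    """
    if not 1 <= S <= grid.K:
        raise ValueError("S must lie in 1..K")
    a = prior.alpha if alpha is None else alpha
    base = prior.base
    if mu is not None or sigma is not None:
        base = BaseDistribution(base.mu if mu is None else mu,
                                base.sigma if sigma is None else sigma)
    F = base.cdf(grid.dose_values[:S])
    cdf = np.concatenate(([0.0], F, [1.0]))
    return a * np.diff(cdf)


def log_prior_density(p, gamma) -> float:
    """Ordered-Dirichlet log prior kernel sum((gamma_i - 1) log(p_i - p_{i-1}))."""
    p = _validate_p(p)
    gamma = np.asarray(gamma, dtype=float)
    inc = np.diff(np.concatenate(([0.0], p, [1.0])))
    return float(np.sum((gamma - 1.0) * np.log(inc)))


def log_dirichlet_normalizer(gamma) -> float:
    """log of the Dirichlet normalising constant for the increment weights.

    Exposed for completeness (the kernel plus this constant integrates to one
    over the ordered simplex); no sampler path uses it.
    """
    gamma = np.asarray(gamma, dtype=float)
    return float(gammaln(gamma.sum()) - gammaln(gamma).sum())


def log_likelihood(p, trial: TrialState) -> float:
    """Binomial log-likelihood kernel over the parameterised doses.

    ``p`` must cover at least every tried dose; doses parameterised beyond the
    data (n_k = 0) contribute nothing.
    """
    p = np.asarray(p, dtype=float)
    S = p.size
    if not trial.S <= S <= trial.n.size:
        raise ValueError(f"p has length {p.size}, expected {trial.S}..{trial.n.size}")
    y = trial.y[:S].astype(float)
    n = trial.n[:S].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(p), 0.0) + \
            np.where(n - y > 0, (n - y) * np.log1p(-p), 0.0)
    return float(np.sum(terms))


def log_posterior(p, trial: TrialState, gamma) -> float:
    """Unnormalised log posterior: likelihood kernel + prior kernel."""
    return log_likelihood(p, trial) + log_prior_density(p, gamma)


def conditional_logdensity_p(i: int, p_value: float, p, trial: TrialState,
                             gamma) -> float:
    """Full-conditional log density of ``p_i`` given its neighbours.

    ``i`` is 1-based.  Support is the open interval ``(p_{i-1}, p_{i+1})``
    (with padding ``p_0 = 0``, ``p_{S+1} = 1``); values outside get ``-inf``.
    """
    p = np.asarray(p, dtype=float)
    S = p.size
    if not 1 <= i <= S:
        raise ValueError(f"index {i} outside 1..{S}")
    if not trial.S <= S <= trial.n.size:
        raise ValueError("p must cover every tried dose")
    lo = p[i - 2] if i > 1 else 0.0
    hi = p[i] if i < S else 1.0
    x = float(p_value)
    if not lo < x < hi:
        return -np.inf
    gamma = np.asarray(gamma, dtype=float)
    y = float(trial.y[i - 1])
    ny = float(trial.n[i - 1] - trial.y[i - 1])
    out = (gamma[i - 1] - 1.0) * np.log(x - lo) + (gamma[i] - 1.0) * np.log(hi - x)
    if y > 0:
        out += y * np.log(x)
    if ny > 0:
        out += ny * np.log1p(-x)
    return float(out)


def conditional_logdensity_alpha(alpha_value: float, p, base: BaseDistribution,
                                 trial: TrialState, grid: DoseGrid,
                                 a: float, b: float) -> float:
    """Full-conditional log kernel of the DP precision ``alpha``.

    ``log Gamma(alpha) - sum_i log Gamma(gamma_i(alpha))
    + sum_i (gamma_i(alpha) - 1) log(p_i - p_{i-1}) + (a-1) log alpha - b alpha``
    with the Dirichlet weights recomputed from ``alpha`` at the fixed base.
    """
    if not alpha_value > 0:
        raise ValueError("alpha must be positive")
    p = _validate_p(p)
    S = p.size
    prior = DPPrior(alpha=alpha_value, base=base)
    g = dirichlet_weights(prior, grid, S)
    inc = np.diff(np.concatenate(([0.0], p, [1.0])))
    return float(gammaln(alpha_value) - gammaln(g).sum()
                 + np.sum((g - 1.0) * np.log(inc))
                 + (a - 1.0) * np.log(alpha_value) - b * alpha_value)


def conditional_logweights_mu_sigma(p, alpha: float, prior: DPPrior,
                                    trial: TrialState, grid: DoseGrid):
    """Normalised full-conditional weights of (mu, sigma) on the product grid.

    Returns ``(mu_grid, sigma_grid, W)`` where ``W[i, j]`` is the posterior
    probability of ``(mu_grid[i], sigma_grid[j])``; normalisation is done in
    log space so the result never underflows to all zeros.
    """
    p = _validate_p(p)
    S = p.size
    mu_grid = prior.mu_grid
    sig_grid = prior.sigma_grid
    if mu_grid.size == 0 or sig_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    inc = np.diff(np.concatenate(([0.0], p, [1.0])))
    log_inc = np.log(inc)
    logw = np.empty((mu_grid.size, sig_grid.size))
    for i, m in enumerate(mu_grid):
        for j, s in enumerate(sig_grid):
            g = dirichlet_weights(prior, grid, S, mu=m, sigma=s, alpha=alpha)
            logw[i, j] = -gammaln(g).sum() + np.sum((g - 1.0) * log_inc)
    logw -= logw.max()
    W = np.exp(logw)
    return mu_grid, sig_grid, W / W.sum()


class DoseToxicityModel:
    """Bayesian nonparametric dose-toxicity model for a phase-I trial.

    Ties the accumulated trial data to the DP prior and, on :meth:`fit`, runs
    the ARMS-within-Gibbs sampler to produce a :class:`~ncrm.sampler.DoseToxicityResults`.

    Parameters
    ----------
    trial : TrialState
        Per-dose patient and toxicity counts (at least one tried dose).
    grid : DoseGrid
        Dose labels and target toxicity probability.
    prior : DPPrior
        DP precision, base curve and (if unknown) hyperprior settings.

    Examples
    --------
    >>> grid = DoseGrid(np.arange(1, 9), theta=0.3)
    >>> trial = TrialState.empty(8)
    >>> trial.add_cohort(1, [0, 0, 1])
    >>> model = DoseToxicityModel(trial, grid, DPPrior(alpha=5.0))
    >>> res = model.fit(seed=1)
    >>> res.posterior_mean.shape
    (1,)
    """

    def __init__(self, trial: TrialState, grid: DoseGrid, prior: DPPrior):
        if trial.n.size != grid.K:
            raise ValueError("trial counts and dose grid disagree on K")
        if trial.S < 1:
            raise ValueError("need at least one tried dose to fit")
        self.trial = trial
        self.grid = grid
        self.prior = prior

    @classmethod
    def from_dataframe(cls, df, dose_values, theta: float, prior: DPPrior):
        """Build from a cohort table with columns cohort, dose_level, n, y."""
        grid = DoseGrid(np.asarray(dose_values, dtype=float), theta)
        trial = TrialState.empty(grid.K)
        for _, row in df.sort_values("cohort").iterrows():
            k = int(row["dose_level"])
            n_i, y_i = int(row["n"]), int(row["y"])
            outcomes = [1] * y_i + [0] * (n_i - y_i)
            trial.add_cohort(k, outcomes)
        return cls(trial, grid, prior)

    def fit(self, config=None, init_p=None, seed=None, **kwargs):
        """Run the Gibbs/ARMS sampler and return a results object.

        ``config`` is a :class:`~ncrm.sampler.SamplerConfig`; keyword arguments
        (``n_burnin``, ``n_keep``, ``seed``, ...) override its fields.
        ``init_p`` defaults to the base-curve values at the tried doses.
        """
        from .sampler import SamplerConfig, run_gibbs, DoseToxicityResults

        if config is None:
            config = SamplerConfig()
        if seed is not None:
            kwargs["seed"] = seed
        if kwargs:
            config = config.replace(**kwargs)
        if init_p is None:
            init_p = repair_monotone(
                base_cdf(self.grid.dose_values[: self.trial.S], self.prior.base))
        else:
            init_p = repair_monotone(np.asarray(init_p, dtype=float))
        draws = run_gibbs(self.trial, self.grid, self.prior, init_p, config)
        return DoseToxicityResults(self, draws)
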