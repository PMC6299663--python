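"""ARMS-within-Gibbs sampling of the dose-toxicity posterior.

The joint posterior of the ordered toxicity probabilities ``p_1 < ... < p_S``
(and, when unknown, the DP precision ``alpha`` and base parameters
``mu, sigma``) is explored by a Gibbs cycle: an independence-Metropolis step
for ``alpha`` (uniform proposal on (1, 20)), an exact categorical draw for
``(mu, sigma)`` on their discrete grid, and one adaptive-rejection-Metropolis
(ARMS) transition per tried dose on the full conditional

    pi(p_i | rest) ∝ p_i^{y_i} (1-p_i)^{n_i-y_i}
                     (p_i - p_{i-1})^{gamma_i - 1} (p_{i+1} - p_i)^{gamma_{i+1} - 1}

restricted to (p_{i-1}, p_{i+1}).  ARMS builds a piecewise-linear hull of the
log target from a set of abscissae, samples the implied piecewise-exponential
proposal by inverse CDF, refines the hull with every rejected point, and
finishes with a Metropolis correction so non-log-concave conditionals are
handled exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from . import _kernels as _k
from .model import (DoseGrid, DPPrior, TrialState, conditional_logdensity_alpha,
                    conditional_logweights_mu_sigma)

__all__ = [
    "SamplerConfig",
    "Envelope",
    "PosteriorDraws",
    "build_envelope",
    "sample_piecewise_exponential",
    "arms_draw",
    "mh_update_alpha",
    "gibbs_update_mu_sigma",
    "run_gibbs",
    "posterior_summary",
    "DoseToxicityResults",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings: burn-in, retained draws, ARMS and RNG parameters."""

    n_burnin: int = 700
    n_keep: int = 1000
    n0_init: int = 5
    max_rejects: int = 100
    seed: int = 0
    joint_grid: bool = True

    def __post_init__(self):
        if min(self.n_burnin, self.n_keep, self.n0_init, self.max_rejects) < 1:
            raise ValueError("all sampler counts must be positive")

    def replace(self, **kw) -> "SamplerConfig":
        return _dc_replace(self, **kw)


@dataclass
class Envelope:
    """Piecewise-exponential proposal built from a log-target hull.

    ``abscissae``/``log_values`` are the hull's support points; the hull itself
    is stored as linear pieces with endpoints ``(piece_lo, piece_hi)``, hull
    values at those endpoints and per-piece log integrals whose log-sum is the
    total log mass ``log omega``.
    """

    support: tuple
    abscissae: np.ndarray
    log_values: np.ndarray
    piece_lo: np.ndarray
    piece_hi: np.ndarray
    piece_h_lo: np.ndarray
    piece_h_hi: np.ndarray
    piece_logmass: np.ndarray

    def hull(self, x: float) -> float:
        """Log envelope value at x (vectorised over array input)."""
        xs, lv = self.abscissae, self.log_values
        lo, hi = self.support
        if np.ndim(x) == 0:
            return _k.hull_eval(xs, lv, xs.size, lo, hi, float(x))
        return np.array([_k.hull_eval(xs, lv, xs.size, lo, hi, float(v))
                         for v in np.asarray(x)])

    @property
    def log_total_mass(self) -> float:
        return _k.total_logmass(self.piece_logmass, self.piece_logmass.size)


def build_envelope(log_target, abscissae, support) -> Envelope:
    """Construct the ARMS envelope from a log target and interior abscissae.

    On each inter-abscissa segment the hull is
    ``max(chord below, min(left chord, right chord))`` with undefined chords
    dropped; exterior segments extend the adjacent chord.  For a log-concave
    target this dominates the log target everywhere (the classical adaptive
    rejection property); in general it is only a proposal, corrected later by
    the Metropolis step.
    """
    lo, hi = float(support[0]), float(support[1])
    xs = np.asarray(abscissae, dtype=float)
    if xs.size < 2:
        raise ValueError("need at least two abscissae")
    if not np.all(np.diff(xs) > 0):
        raise ValueError("abscissae must be strictly increasing")
    if xs[0] <= lo or xs[-1] >= hi:
        raise ValueError("abscissae must be strictly inside the support")
    lv = np.array([float(log_target(x)) for x in xs])
    if not np.all(np.isfinite(lv)):
        raise ValueError("log target must be finite at every abscissa")
    return _envelope_from_points(xs, lv, lo, hi)


def _envelope_from_points(xs, lv, lo, hi) -> Envelope:
    m = xs.size
    cap = _k._PIECES_PER_SEG * (m + 2)
    pa = np.empty(cap)
    pb = np.empty(cap)
    pha = np.empty(cap)
    phb = np.empty(cap)
    plm = np.empty(cap)
    npieces = _k.build_pieces(xs, lv, m, lo, hi, pa, pb, pha, phb, plm)
    return Envelope((lo, hi), xs, lv, pa[:npieces].copy(), pb[:npieces].copy(),
                    pha[:npieces].copy(), phb[:npieces].copy(),
                    plm[:npieces].copy())


def sample_piecewise_exponential(env: Envelope, rng: np.random.Generator) -> float:
    """Draw from the density proportional to exp(hull) on the support."""
    if not np.isfinite(env.log_total_mass):
        raise ValueError("degenerate envelope: zero total mass")
    u_seg = rng.random()
    u_pos = rng.random()
    return _k.sample_pieces(env.piece_lo, env.piece_hi, env.piece_h_lo,
                            env.piece_h_hi, env.piece_logmass,
                            env.piece_logmass.size, u_seg, u_pos)


def arms_draw(log_target, support, previous: float, config: SamplerConfig,
              rng: np.random.Generator, return_info: bool = False):
    """One ARMS transition for an arbitrary log target on an interval.

    Mirrors the jitted per-coordinate kernel: rejection sampling from the
    envelope with adaptive refinement, then the Metropolis correction using
    ``min(pi, exp h)`` at the previous and proposed points.  With
    ``return_info=True`` also returns a dict with the rejection count and
    whether the Metropolis step rejected the proposal.
    """
    lo, hi = float(support[0]), float(support[1])
    if not lo < previous < hi:
        raise ValueError("previous state must lie inside the support")
    span = hi - lo
    m = config.n0_init
    xs = list(lo + span * (np.arange(1, m + 1)) / (m + 1.0))
    lv = [float(log_target(x)) for x in xs]
    n_rejects = 0
    x_star = h_star = lt_star = None
    for _ in range(config.max_rejects):
        env = _envelope_from_points(np.array(xs), np.array(lv), lo, hi)
        x = sample_piecewise_exponential(env, rng)
        if not lo < x < hi:
            n_rejects += 1
            continue
        h = env.hull(x)
        lt = float(log_target(x))
        if math.log(rng.random()) <= lt - h:
            x_star, h_star, lt_star = x, h, lt
            break
        n_rejects += 1
        pos = int(np.searchsorted(xs, x))
        xs.insert(pos, x)
        lv.insert(pos, lt)
    if x_star is None:
        raise RuntimeError("ARMS rejection loop exceeded max_rejects")
    lt_prev = float(log_target(previous))
    h_prev = env.hull(previous)
    log_acc = (lt_star + min(lt_prev, h_prev)) - (lt_prev + min(lt_star, h_star))
    mh_rejected = not (log_acc >= 0.0 or math.log(rng.random()) <= log_acc)
    out = previous if mh_rejected else x_star
    if return_info:
        return out, {"n_rejects": n_rejects, "mh_rejected": mh_rejected}
    return out


def mh_update_alpha(current: float, p, prior: DPPrior, trial: TrialState,
                    grid: DoseGrid, rng: np.random.Generator) -> float:
    """Independence-Metropolis update of the DP precision, proposal U(1, 20)."""
    prop = rng.uniform(1.0, 20.0)
    cur_k = conditional_logdensity_alpha(current, p, prior.base, trial, grid,
                                         prior.a, prior.b)
    prop_k = conditional_logdensity_alpha(prop, p, prior.base, trial, grid,
                                          prior.a, prior.b)
    if prop_k - cur_k >= 0.0 or math.log(rng.random()) <= prop_k - cur_k:
        return float(prop)
    return float(current)


def gibbs_update_mu_sigma(p, alpha: float, prior: DPPrior, trial: TrialState,
                          grid: DoseGrid, rng: np.random.Generator,
                          joint: bool = True):
    """Exact categorical draw of (mu, sigma) from their grid conditional.

    ``joint=True`` draws the pair from the product grid in one categorical
    step; ``joint=False`` mimics a sequential mu-then-sigma scan (the
    stationary distribution is the same).
    """
    mu_grid, sig_grid, W = conditional_logweights_mu_sigma(p, alpha, prior,
                                                           trial, grid)
    if joint:
        flat = W.ravel()
        idx = rng.choice(flat.size, p=flat / flat.sum())
        return float(mu_grid[idx // sig_grid.size]), float(sig_grid[idx % sig_grid.size])
    wm = W.sum(axis=1)
    i = rng.choice(mu_grid.size, p=wm / wm.sum())
    ws = W[i]
    j = rng.choice(sig_grid.size, p=ws / ws.sum())
    return float(mu_grid[i]), float(sig_grid[j])


@dataclass
class PosteriorDraws:
    """Retained joint MCMC draws of (p, alpha, mu, sigma)."""

    p: np.ndarray
    alpha: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    config: SamplerConfig

    @property
    def n_keep(self) -> int:
        return self.p.shape[0]

    @property
    def S(self) -> int:
        return self.p.shape[1]


def run_gibbs(trial: TrialState, grid: DoseGrid, prior: DPPrior,
              init_p, config: SamplerConfig) -> PosteriorDraws:
    """Run the full chain and return the retained draws.

    With ``prior.alpha_fixed`` the hyperparameter steps are skipped and the
    Dirichlet weights stay at their values under the declared (alpha, mu,
    sigma); otherwise alpha follows its Gamma(a, b) hyperprior (explored
    through the U(1,20) proposal) and (mu, sigma) their discrete grids.

    The number of parameterised doses is ``len(init_p)``; it must cover every
    tried dose.  Passing a full-length ``init_p`` with an all-zero trial
    samples the DP prior itself (useful for prior-recovery checks).
    """
    init_p = np.asarray(init_p, dtype=float)
    S = init_p.size
    if not trial.S <= S <= grid.K:
        raise ValueError("init_p must cover the tried doses (S <= len <= K)")
    inc = np.diff(np.concatenate(([0.0], init_p, [1.0])))
    if np.any(inc <= 0):
        raise ValueError("init_p must be strictly increasing inside (0, 1)")
    if prior.alpha_fixed:
        alpha0, mu0, sig0 = prior.alpha, prior.base.mu, prior.base.sigma
        mu_grid = np.array([mu0])
        sig_grid = np.array([sig0])
        update_hyper = False
    else:
        alpha0 = prior.a / prior.b
        mu_grid = prior.mu_grid
        sig_grid = prior.sigma_grid
        mu0 = float(mu_grid[mu_grid.size // 2])
        sig0 = float(sig_grid[sig_grid.size // 2])
        update_hyper = True
    p_out, a_out, m_out, s_out = _k.gibbs_chain(
        trial.y[:S].astype(np.float64), trial.n[:S].astype(np.float64), S,
        grid.dose_values, float(alpha0), float(mu0), float(sig0),
        float(prior.a), float(prior.b), update_hyper, config.joint_grid,
        mu_grid.astype(np.float64), sig_grid.astype(np.float64),
        init_p, config.n_burnin, config.n_keep, config.n0_init,
        config.max_rejects, int(config.seed) % (2**31 - 1))
    return PosteriorDraws(p_out, a_out, m_out, s_out, config)


def posterior_summary(draws: PosteriorDraws, theta: float):
    """Per-dose posterior means and Pr(p_k < theta) over the tried doses."""
    if draws.n_keep == 0:
        raise ValueError("no retained draws")
    p_hat = draws.p.mean(axis=0)
    prob_below = (draws.p < theta).mean(axis=0)
    return p_hat, prob_below


class DoseToxicityResults:
    """Posterior summaries of a fitted :class:`~ncrm.model.DoseToxicityModel`.

    Carries the retained draws; exposes posterior means, posterior
    probabilities of being below the target, the MTD estimate and a printable
    summary table.
    """

    def __init__(self, model, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._p_hat, self._prob_below = posterior_summary(draws, model.grid.theta)

    @property
    def posterior_mean(self) -> np.ndarray:
        """Posterior mean toxicity probability at each tried dose."""
        return self._p_hat

    @property
    def prob_below_target(self) -> np.ndarray:
        """Pr(p_k < theta) at each tried dose."""
        return self._prob_below

    def prob_below(self, theta: float | None = None) -> np.ndarray:
        if theta is None:
            return self._prob_below
        return (self.draws.p < theta).mean(axis=0)

    @property
    def mtd(self) -> int:
        """1-based tried dose whose posterior mean is closest to theta."""
        from .design import select_mtd
        return select_mtd(self._p_hat, self.model.grid.theta)

    def summary(self) -> str:
        import pandas as pd

        S = self.draws.S
        theta = self.model.grid.theta
        df = pd.DataFrame({
            "dose": np.arange(1, S + 1),
            "n": self.model.trial.n[:S],
            "y": self.model.trial.y[:S],
            "post_mean": np.round(self._p_hat, 4),
            "prob_below_target": np.round(self._prob_below, 4),
        })
        head = (f"Nonparametric CRM posterior (theta={theta}, "
                f"{self.draws.n_keep} draws after {self.draws.config.n_burnin} "
                f"burn-in)\nEstimated MTD: dose {self.mtd}")
        return head + "\n" + df.to_string(index=False)

    def to_frame(self):
        import pandas as pd

        S = self.draws.S
        return pd.DataFrame({"dose": np.arange(1, S + 1),
                             "post_mean": self._p_hat,
                             "prob_below_target": self._prob_below})

    def plot_dose_toxicity(self, ax=None, true_p=None):
        """Plot posterior-mean curve against the base curve (and truth)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.grid.dose_values
        S = self.draws.S
        ax.plot(d, self.model.prior.base.cdf(d), "o-", label="base $F_0$")
        ax.plot(d[:S], self._p_hat, "^-", label="posterior mean")
        if true_p is not None:
            ax.plot(d, true_p, "*-", label="true")
        ax.axhline(self.model.grid.theta, ls=":", c="grey")
        ax.set_xlabel("dose level")
        ax.set_ylabel("toxicity probability")
        ax.legend()
        return ax
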