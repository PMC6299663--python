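"""Two-stage Bayesian adaptive dose-finding design and trial orchestration.

Stage I escalates from the lowest dose one level per cohort until the first
dose-limiting toxicity is observed.  Stage II then repeats the current dose
for one cohort and, after every subsequent cohort, refits the posterior and
applies the threshold rules: escalate one level when
``Pr(p_current < theta) > c_e``, de-escalate one level when it is below
``c_d`` (with ``c_e + c_d > 1``), otherwise stay.  Moves never exceed one
dose level and are clipped to the dose grid.  When the maximum sample size is
reached, the tried dose whose posterior-mean toxicity is closest to the
target is declared the MTD.

The same orchestration runs the parametric CRM comparators: they start at the
lowest dose, refit the posterior mean of the model parameter after every
cohort, and assign the model-recommended dose clipped to one level of change
per cohort (which in particular forbids skipping untried levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crm import ParametricCRM
from .model import DoseGrid, DPPrior, TrialState, repair_monotone
from .sampler import SamplerConfig, run_gibbs, posterior_summary

__all__ = ["DesignConfig", "TrialRecord", "startup_next", "stage2_decision",
           "select_mtd", "run_trial"]

ENGINES = ("ncrm", "crm-power", "crm-logistic")


@dataclass(frozen=True)
class DesignConfig:
    """Trial-size and threshold settings for the adaptive design."""

    N: int = 60
    m: int = 3
    J: int = 20
    c_e: float = 0.6
    c_d: float = 0.6
    engine: str = "ncrm"

    def __post_init__(self):
        if self.N != self.J * self.m:
            raise ValueError("need N = J * m")
        if not (0 < self.c_e < 1 and 0 < self.c_d < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if not self.c_e + self.c_d > 1:
            raise ValueError("thresholds must satisfy c_e + c_d > 1")
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")


def startup_next(trial: TrialState, grid: DoseGrid):
    """Stage-I transition from the last recorded cohort.

    Returns ``(next_dose, enter_stage2)``: on any toxicity in the last cohort
    the design enters stage II and the next cohort repeats the same dose;
    otherwise the next cohort moves one level up (staying at the top dose).
    """
    if not trial.cohort_log:
        return 1, False
    _, dose, outcomes = trial.cohort_log[-1]
    if int(np.sum(outcomes)) >= 1:
        return dose, True
    return min(dose + 1, grid.K), False


def stage2_decision(current: int, prob_below: float, config: DesignConfig,
                    grid: DoseGrid) -> int:
    """Threshold rule for the next cohort's dose (one-level moves, clipped)."""
    if prob_below > config.c_e:
        return min(current + 1, grid.K)
    if prob_below < config.c_d:
        return max(current - 1, 1)
    return current


def select_mtd(p_hat, theta: float) -> int:
    """1-based tried dose with posterior-mean toxicity closest to theta.

    Ties resolve to the lower dose.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    if p_hat.size == 0:
        raise ValueError("need at least one tried dose")
    return int(np.argmin(np.abs(p_hat - theta))) + 1


@dataclass
class TrialRecord:
    """Complete record of one simulated (or executed) trial."""

    assignments: list  # 1-based dose per cohort
    outcomes: list  # binary outcome arrays per cohort
    p_hat_trace: list  # per-cohort posterior means (None before any fit)
    mtd: int
    n: np.ndarray  # final per-dose patient counts
    y: np.ndarray  # final per-dose toxicity counts
    engine: str
    final_p_hat: np.ndarray = field(default=None)

    @property
    def total_toxicities(self) -> int:
        return int(self.y.sum())


def _fit_ncrm(trial, grid, prior, sampler, init_skeleton, rng):
    S = trial.S
    if init_skeleton is not None:
        init_p = repair_monotone(np.asarray(init_skeleton, dtype=float)[:S])
    else:
        init_p = repair_monotone(prior.base.cdf(grid.dose_values[:S]))
    cfg = sampler.replace(seed=int(rng.integers(1, 2**31 - 1)))
    draws = run_gibbs(trial, grid, prior, init_p, cfg)
    return posterior_summary(draws, grid.theta)


def run_trial(true_p, grid: DoseGrid, config: DesignConfig, engine_model,
              sampler: SamplerConfig | None = None,
              rng: np.random.Generator | None = None,
              init_skeleton=None) -> TrialRecord:
    """Simulate one complete trial under known true toxicity probabilities.

    Parameters
    ----------
    true_p : array-like
        True per-dose toxicity probabilities used to generate outcomes.
    engine_model : DPPrior or ParametricCRM
        The dose-toxicity engine matching ``config.engine``.
    init_skeleton : array-like, optional
        Initial value of the toxicity vector for each posterior refit
        (truncated to the tried doses); defaults to the base-curve values.
    """
    from .simulate import sample_cohort_outcomes

    true_p = np.asarray(true_p, dtype=float)
    if true_p.size != grid.K:
        raise ValueError("true_p must give one probability per dose level")
    if rng is None:
        rng = np.random.default_rng()
    if sampler is None:
        sampler = SamplerConfig()
    is_ncrm = config.engine == "ncrm"
    if is_ncrm and not isinstance(engine_model, DPPrior):
        raise TypeError("ncrm engine requires a DPPrior")
    if not is_ncrm and not isinstance(engine_model, ParametricCRM):
        raise TypeError("crm engines require a ParametricCRM")

    trial = TrialState.empty(grid.K)
    current = 1
    stage2 = False
    assignments, outcomes_log, trace = [], [], []
    crm_cohorts = []
    p_hat = None
    for j in range(1, config.J + 1):
        _, outcomes = sample_cohort_outcomes(true_p[current - 1], config.m, rng)
        trial.add_cohort(current, outcomes)
        assignments.append(current)
        outcomes_log.append(outcomes)
        if is_ncrm:
            if not stage2:
                nxt, entered = startup_next(trial, grid)
                if entered:
                    stage2 = True
                    current = nxt  # repeat cohort at the same dose
                    trace.append(None)
                    continue
                trace.append(None)
                current = nxt
                continue
            p_hat, prob_below = _fit_ncrm(trial, grid, engine_model, sampler,
                                          init_skeleton, rng)
            trace.append(p_hat)
            if j < config.J:
                current = stage2_decision(current, prob_below[current - 1],
                                          config, grid)
        else:
            crm_cohorts.append((current, config.m, int(np.sum(outcomes))))
            res = engine_model.fit(crm_cohorts, grid.theta)
            p_hat = res.p_hat
            trace.append(p_hat)
            if j < config.J:
                proposed = res.next_dose
                current = int(np.clip(proposed, current - 1, current + 1))
    # final fit for MTD selection (stage I may have ended without any fit)
    if is_ncrm and p_hat is None:
        p_hat, _ = _fit_ncrm(trial, grid, engine_model, sampler,
                             init_skeleton, rng)
    S = trial.S
    mtd = select_mtd(np.asarray(p_hat)[:S], grid.theta)
    return TrialRecord(assignments, outcomes_log, trace, mtd,
                       trial.n.copy(), trial.y.copy(), config.engine,
                       final_p_hat=np.asarray(p_hat))
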