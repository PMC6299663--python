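"""Toxicity scenarios, replicated-trial engine and operating characteristics.

Six built-in scenarios (eight dose levels, target toxicity 0.3) cover a
steadily increasing curve with the MTD in the middle, a sudden jump above the
MTD, flat curves with the MTD at or near the top dose, and curves where every
dose is at or above the target.  Each scenario carries its true per-dose
toxicities, an indifference-interval skeleton, and the (mu, sigma) of the
normal base curve whose median matches the prior MTD guess.

Operating characteristics aggregate replicated trials: the per-dose
probability of being selected as MTD, the average per-dose patient
allocation, and the average number of dose-limiting toxicities per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crm import ParametricCRM, Skeleton, skeleton_getprior
from .design import DesignConfig, TrialRecord, run_trial
from .model import BaseDistribution, DoseGrid, DPPrior
from .sampler import SamplerConfig

__all__ = ["Scenario", "OperatingCharacteristics", "builtin_scenarios",
           "sample_cohort_outcomes", "run_operating_characteristics",
           "calibrate_thresholds", "make_engine"]


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario: true curve, skeleton and base-curve centre."""

    id: int
    true_p: np.ndarray
    target_dose: int | None  # 1-based true MTD, None if no dose hits target
    skeleton: Skeleton
    base_params: tuple  # (mu, sigma) of the normal base curve
    theta: float = 0.3

    def __post_init__(self):
        tp = np.asarray(self.true_p, dtype=float)
        if np.any(np.diff(tp) < 0) or np.any(tp < 0) or np.any(tp > 1):
            raise ValueError("true toxicities must be nondecreasing in [0, 1]")
        object.__setattr__(self, "true_p", tp)

    @property
    def grid(self) -> DoseGrid:
        return DoseGrid(np.arange(1, self.true_p.size + 1, dtype=float),
                        self.theta)

    @property
    def base(self) -> BaseDistribution:
        return BaseDistribution(*self.base_params)


# (true_p, delta, nu, (mu, sigma), target_dose); theta = 0.3 throughout
_SCENARIO_TABLE = {
    1: ((0.05, 0.08, 0.12, 0.20, 0.30, 0.45, 0.60, 0.70), 0.05, 5, (6.0, 2.0), 5),
    2: ((0.05, 0.08, 0.12, 0.20, 0.30, 0.60, 0.80, 0.90), 0.075, 5, (6.0, 2.0), 5),
    3: ((0.01, 0.05, 0.10, 0.14, 0.18, 0.22, 0.25, 0.30), 0.03, 8, (10.0, 5.0), 8),
    4: ((0.01, 0.05, 0.08, 0.12, 0.16, 0.20, 0.24, 0.26), 0.04, 8, (10.0, 5.0), None),
    5: ((0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95), 0.07, 1, (3.0, 4.0), 1),
    6: ((0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.80), 0.05, 1, (3.0, 4.0), None),
}


def builtin_scenarios() -> dict[int, Scenario]:
    """The six built-in toxicity scenarios (theta = 0.3, K = 8)."""
    out = {}
    for sid, (tp, delta, nu, musig, target) in _SCENARIO_TABLE.items():
        sk = skeleton_getprior(delta, 0.3, nu, len(tp))
        out[sid] = Scenario(sid, np.array(tp), target, sk, musig)
    return out


def make_engine(scenario: Scenario, engine: str, alpha: float = 5.0,
                alpha_fixed: bool = True, a: float = 2.0, b: float = 2.0,
                r: float = 1.0, grid_size: int = 10):
    """Build the dose-toxicity engine for a scenario.

    For ``"ncrm"`` returns a :class:`DPPrior` centred on the scenario's base
    curve; for ``"crm-power"`` / ``"crm-logistic"`` a :class:`ParametricCRM`
    on the scenario skeleton.
    """
    if engine == "ncrm":
        return DPPrior(alpha=alpha, base=scenario.base, alpha_fixed=alpha_fixed,
                       a=a, b=b, r=r, grid_size=grid_size)
    if engine == "crm-power":
        return ParametricCRM(scenario.skeleton, variant="power")
    if engine == "crm-logistic":
        return ParametricCRM(scenario.skeleton, variant="logistic")
    raise ValueError(f"unknown engine {engine!r}")


def sample_cohort_outcomes(p_true: float, m: int, rng: np.random.Generator):
    """m independent Bernoulli(p_true) toxicity outcomes and their count."""
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must lie in [0, 1]")
    outcomes = (rng.random(m) < p_true).astype(np.int64)
    return int(outcomes.sum()), outcomes


@dataclass
class OperatingCharacteristics:
    """Aggregated results of replicated simulated trials."""

    selection_prob: np.ndarray
    avg_patients: np.ndarray
    avg_toxicities: float
    n_trials: int
    seed: int
    engine: str
    scenario_id: int | None = None

    @property
    def avg_toxicities_rounded(self) -> int:
        return int(round(self.avg_toxicities))

    def to_frame(self) -> pd.DataFrame:
        K = self.selection_prob.size
        return pd.DataFrame(
            {"dose": np.arange(1, K + 1),
             "selection_prob": self.selection_prob,
             "avg_patients": self.avg_patients})

    def to_row(self) -> pd.DataFrame:
        """One wide row per engine, mirroring a printed OC table."""
        K = self.selection_prob.size
        data = {"scenario": self.scenario_id, "engine": self.engine,
                "n_trials": self.n_trials}
        for k in range(K):
            data[f"sel_{k + 1}"] = round(float(self.selection_prob[k]), 3)
        for k in range(K):
            data[f"pat_{k + 1}"] = round(float(self.avg_patients[k]), 3)
        data["avg_tox"] = round(float(self.avg_toxicities), 3)
        data["avg_tox_rounded"] = self.avg_toxicities_rounded
        return pd.DataFrame([data])


def _trial_seeds(seed: int, n_trials: int) -> np.ndarray:
    """Independent, order-insensitive per-trial seeds from the master seed."""
    return np.random.SeedSequence(seed).generate_state(n_trials) & 0x7FFFFFFF


def run_operating_characteristics(scenario: Scenario, config: DesignConfig,
                                  engine_model, sampler: SamplerConfig,
                                  n_trials: int, seed: int,
                                  progress: bool = False,
                                  collect_records: bool = False):
    """Replicate trials and aggregate their operating characteristics."""
    if n_trials < 1:
        raise ValueError("need n_trials >= 1")
    grid = scenario.grid
    K = grid.K
    sel = np.zeros(K)
    pat = np.zeros(K)
    tox = 0.0
    seeds = _trial_seeds(seed, n_trials)
    records: list[TrialRecord] = []
    iterator = range(n_trials)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc=f"scenario {scenario.id} {config.engine}")
    for t in iterator:
        rng = np.random.default_rng(int(seeds[t]))
        rec = run_trial(scenario.true_p, grid, config, engine_model,
                        sampler=sampler, rng=rng,
                        init_skeleton=scenario.skeleton.p0)
        sel[rec.mtd - 1] += 1
        pat += rec.n
        tox += rec.total_toxicities
        if collect_records:
            records.append(rec)
    oc = OperatingCharacteristics(sel / n_trials, pat / n_trials,
                                  tox / n_trials, n_trials, seed,
                                  config.engine, scenario.id)
    if collect_records:
        return oc, records
    return oc


def calibrate_thresholds(scenario: Scenario, engine_model,
                         sampler: SamplerConfig, n_pilot: int = 50,
                         seed: int = 0, threshold_grid=None,
                         design_kwargs=None) -> tuple[float, float, pd.DataFrame]:
    """Grid-search (c_e, c_d) maximising correct-selection probability.

    Evaluates each admissible threshold pair (``c_e + c_d > 1``) on
    ``n_pilot`` replicated trials and returns the pair with the highest
    probability of selecting the scenario's target dose (the dose closest to
    target when no dose hits it exactly), with the full pilot table.
    """
    if threshold_grid is None:
        threshold_grid = np.arange(0.50, 0.901, 0.05)
    target = scenario.target_dose
    if target is None:
        target = int(np.argmin(np.abs(scenario.true_p - scenario.theta))) + 1
    rows = []
    design_kwargs = design_kwargs or {}
    for ce in threshold_grid:
        for cd in threshold_grid:
            if ce + cd <= 1.0:
                continue
            config = DesignConfig(c_e=round(float(ce), 2),
                                  c_d=round(float(cd), 2), **design_kwargs)
            oc = run_operating_characteristics(scenario, config, engine_model,
                                               sampler, n_pilot, seed)
            rows.append({"c_e": config.c_e, "c_d": config.c_d,
                         "correct_selection": oc.selection_prob[target - 1],
                         "avg_toxicities": oc.avg_toxicities})
    table = pd.DataFrame(rows)
    best = table.loc[table["correct_selection"].idxmax()]
    return float(best["c_e"]), float(best["c_d"]), table
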