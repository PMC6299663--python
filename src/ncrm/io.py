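"""Configuration and file I/O: YAML run configs, trial CSVs, result tables.

Trial data travel as a cohort table with header ``cohort,dose_level,n,y``
(1-based dose levels); operating-characteristic tables and per-cohort traces
are written as CSV with fixed decimal formatting (3 dp for selection
probabilities, 4 dp for posterior-mean traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .crm import ParametricCRM, Skeleton, skeleton_getprior
from .design import DesignConfig
from .model import BaseDistribution, DoseGrid, DPPrior, TrialState
from .sampler import SamplerConfig

__all__ = ["RunConfig", "load_config", "save_config", "read_trial_csv",
           "trial_to_frame", "write_oc", "write_trace"]

TRIAL_HEADER = ["cohort", "dose_level", "n", "y"]


@dataclass
class RunConfig:
    """Composite configuration for a fit, trial or simulation run."""

    grid: DoseGrid
    prior: DPPrior
    design: DesignConfig
    sampler: SamplerConfig
    scenario_id: int | None = None
    true_p: np.ndarray | None = None
    skeleton: Skeleton | None = None
    n_trials: int = 1000
    seed: int = 0
    output: str | None = None
    crm_variant: str = "power"

    def engine_model(self):
        """The engine object implied by the design's engine field."""
        if self.design.engine == "ncrm":
            return self.prior
        if self.skeleton is None:
            raise ValueError("crm engines need a skeleton section")
        variant = "power" if self.design.engine == "crm-power" else "logistic"
        return ParametricCRM(self.skeleton, variant=variant)


def _as_dict(cfg: RunConfig) -> dict:
    out = {
        "grid": {"dose_values": [float(v) for v in cfg.grid.dose_values],
                 "theta": cfg.grid.theta},
        "prior": {"alpha": cfg.prior.alpha, "alpha_fixed": cfg.prior.alpha_fixed,
                  "mu": cfg.prior.base.mu, "sigma": cfg.prior.base.sigma,
                  "a": cfg.prior.a, "b": cfg.prior.b, "r": cfg.prior.r,
                  "grid_size": cfg.prior.grid_size},
        "design": {"N": cfg.design.N, "m": cfg.design.m, "J": cfg.design.J,
                   "c_e": cfg.design.c_e, "c_d": cfg.design.c_d,
                   "engine": cfg.design.engine},
        "sampler": {"n_burnin": cfg.sampler.n_burnin,
                    "n_keep": cfg.sampler.n_keep,
                    "n0_init": cfg.sampler.n0_init,
                    "max_rejects": cfg.sampler.max_rejects,
                    "joint_grid": cfg.sampler.joint_grid},
        "n_trials": cfg.n_trials,
        "seed": cfg.seed,
    }
    if cfg.scenario_id is not None:
        out["scenario"] = cfg.scenario_id
    if cfg.true_p is not None:
        out["true_p"] = [float(v) for v in cfg.true_p]
    if cfg.skeleton is not None:
        out["skeleton"] = {"delta": cfg.skeleton.delta, "nu": cfg.skeleton.nu}
    if cfg.output is not None:
        out["output"] = cfg.output
    return out


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a plain mapping, applying defaults."""
    try:
        g = raw.get("grid", {})
        dose_values = g.get("dose_values", list(range(1, 9)))
        theta = float(g.get("theta", 0.3))
        grid = DoseGrid(np.asarray(dose_values, dtype=float), theta)

        pr = raw.get("prior", {})
        base = BaseDistribution(float(pr.get("mu", 6.0)),
                                float(pr.get("sigma", 2.0)))
        prior = DPPrior(alpha=float(pr.get("alpha", 5.0)), base=base,
                        alpha_fixed=bool(pr.get("alpha_fixed", True)),
                        a=float(pr.get("a", 2.0)), b=float(pr.get("b", 2.0)),
                        r=float(pr.get("r", 1.0)),
                        grid_size=int(pr.get("grid_size", 10)))

        de = raw.get("design", {})
        design = DesignConfig(N=int(de.get("N", 60)), m=int(de.get("m", 3)),
                              J=int(de.get("J", 20)),
                              c_e=float(de.get("c_e", 0.6)),
                              c_d=float(de.get("c_d", 0.6)),
                              engine=de.get("engine", "ncrm"))

        sa = raw.get("sampler", {})
        sampler = SamplerConfig(n_burnin=int(sa.get("n_burnin", 700)),
                                n_keep=int(sa.get("n_keep", 1000)),
                                n0_init=int(sa.get("n0_init", 5)),
                                max_rejects=int(sa.get("max_rejects", 100)),
                                seed=int(raw.get("seed", 0)),
                                joint_grid=bool(sa.get("joint_grid", True)))
    except (ValueError, TypeError) as err:
        raise ValueError(f"invalid configuration: {err}") from err

    skeleton = None
    if "skeleton" in raw:
        sk = raw["skeleton"]
        if "values" in sk:
            skeleton = Skeleton(np.asarray(sk["values"], dtype=float),
                                float(sk.get("delta", np.nan)),
                                int(sk.get("nu", 1)))
        else:
            skeleton = skeleton_getprior(float(sk["delta"]), theta,
                                         int(sk["nu"]), grid.K)
    true_p = None
    if "true_p" in raw:
        true_p = np.asarray(raw["true_p"], dtype=float)
        if true_p.size != grid.K:
            raise ValueError("true_p length must match the dose grid")
    return RunConfig(grid=grid, prior=prior, design=design, sampler=sampler,
                     scenario_id=raw.get("scenario"), true_p=true_p,
                     skeleton=skeleton, n_trials=int(raw.get("n_trials", 1000)),
                     seed=int(raw.get("seed", 0)), output=raw.get("output"))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=True)


def read_trial_csv(path, K: int | None = None) -> TrialState:
    """Parse a cohort table CSV into a TrialState.

    Validates the header, ``y <= n`` per cohort, and contiguity of tried
    doses from the lowest level.
    """
    df = pd.read_csv(path)
    if list(df.columns) != TRIAL_HEADER:
        raise ValueError(f"expected header {','.join(TRIAL_HEADER)}, "
                         f"got {','.join(map(str, df.columns))}")
    if df.empty:
        raise ValueError("trial CSV contains no cohorts")
    if K is None:
        K = int(df["dose_level"].max())
    if (df["dose_level"] < 1).any() or (df["dose_level"] > K).any():
        raise ValueError("dose_level outside 1..K")
    trial = TrialState.empty(K)
    for _, row in df.sort_values("cohort").iterrows():
        n_i, y_i = int(row["n"]), int(row["y"])
        if y_i > n_i:
            raise ValueError("cohort has y > n")
        trial.add_cohort(int(row["dose_level"]),
                         [1] * y_i + [0] * (n_i - y_i))
    return trial


def trial_to_frame(trial: TrialState) -> pd.DataFrame:
    rows = [{"cohort": i, "dose_level": d, "n": len(o), "y": int(np.sum(o))}
            for i, d, o in trial.cohort_log]
    return pd.DataFrame(rows, columns=TRIAL_HEADER)


def write_oc(oc_rows, path) -> None:
    """Write one or more OC result rows to CSV (3 dp on probabilities)."""
    if not isinstance(oc_rows, (list, tuple)):
        oc_rows = [oc_rows]
    df = pd.concat([oc.to_row() for oc in oc_rows], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.3f")


def write_trace(record, K: int, path) -> None:
    """Per-cohort trace CSV: cohort, dose, outcomes, posterior means (4 dp)."""
    rows = []
    m = max(len(o) for o in record.outcomes)
    for i, (dose, outc, ph) in enumerate(zip(record.assignments,
                                             record.outcomes,
                                             record.p_hat_trace), start=1):
        row = {"i": i, "x_i": dose}
        for t in range(m):
            row[f"y_i{t + 1}"] = int(outc[t]) if t < len(outc) else ""
        for k in range(K):
            if ph is not None and k < len(ph):
                row[f"phat_{k + 1}"] = f"{ph[k]:.4f}"
            else:
                row[f"phat_{k + 1}"] = ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
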