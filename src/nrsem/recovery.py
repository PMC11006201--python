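"""Parameter-recovery and coverage studies against the synthetic truth.

Two harnesses:

* :func:`recovery_study` — repeatedly generate data from the default
  population (continuous-indicator mode, so the analysis model is correctly
  specified), fit the truth-structure model, and summarise bias per free
  structural coefficient.
* :func:`coverage_study` — a fast observed-variable version of the
  depression <-> anxiety loop (same structural coefficients, strong
  instruments) where each replication also runs a case bootstrap, so
  percentile-CI coverage of the loop paths can be estimated within a
  reasonable compute budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem import SemModel, bootstrap_fit, fit_sem
from .simulate import DEFAULT_B, DEFAULT_GAMMA, ITEM_BLOCKS, PopulationSpec, generate_dataset


def truth_structure() -> dict[str, list[str]]:
    """Regression map exactly matching the generator's nonzero paths."""
    regs: dict[str, list[str]] = {}
    for out, src in list(DEFAULT_B) + list(DEFAULT_GAMMA):
        regs.setdefault(out, []).append(src)
    return regs


def truth_values() -> dict[str, float]:
    """name -> true coefficient, named like FitResult estimates."""
    vals = {f"{o}~{s}": v for (o, s), v in DEFAULT_B.items()}
    vals.update({f"{o}~{s}": v for (o, s), v in DEFAULT_GAMMA.items()})
    return vals


@dataclass
class RecoveryResult:
    estimates: pd.DataFrame       # one row per replication, one column per path
    truth: dict[str, float]
    n_converged: int
    n_reps: int

    @property
    def mean_bias(self) -> pd.Series:
        t = pd.Series(self.truth)
        return self.estimates.mean() - t.reindex(self.estimates.columns)

    @property
    def max_abs_mean_bias(self) -> float:
        return float(self.mean_bias.abs().max())


def recovery_study(n_reps: int = 50, n: int = 2000, seed: int = 0) -> RecoveryResult:
    """Fit the correctly specified item-level model to continuous-indicator
    draws from the default population; returns per-path estimates."""
    regs = truth_structure()
    truth = truth_values()
    meas = {c: [f"{pre}{i}" for i in range(1, k + 1)]
            for c, (pre, k, _, _) in ITEM_BLOCKS.items()}
    rows = []
    ok = 0
    for r in range(n_reps):
        ds = generate_dataset(PopulationSpec(n=n, ordinal=False, missing_rate=0.0),
                              seed=seed + r)
        model = SemModel(measurement=meas, regressions=regs, psi="full")
        fit = fit_sem(model, ds.table)
        ok += fit.converged
        rows.append({k: fit.estimates[k] for k in truth})
    return RecoveryResult(estimates=pd.DataFrame(rows), truth=truth,
                          n_converged=ok, n_reps=n_reps)


# ---------------------------------------------------------------------------
# Fast observed-variable loop scenario for bootstrap coverage
# ---------------------------------------------------------------------------

LOOP_B = np.array([[0.0, DEFAULT_B[("depression", "anxiety")]],
                   [DEFAULT_B[("anxiety", "depression")], 0.0]])
LOOP_GAMMA = np.array([[0.6, 0.0, -0.06],
                       [0.0, 0.5, 0.54]])   # dep-instrument, anx-instrument, stress
LOOP_PSI = np.array([[0.30, 0.05], [0.05, 0.30]])


def simulate_loop_observed(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Observed two-equation depression <-> anxiety system with one strong
    unique instrument per side plus a shared stress score."""
    x = rng.multivariate_normal(np.zeros(3), np.eye(3), size=n)
    zeta = rng.multivariate_normal(np.zeros(2), LOOP_PSI, size=n)
    eta = np.linalg.solve(np.eye(2) - LOOP_B, LOOP_GAMMA @ x.T + zeta.T).T
    return pd.DataFrame({"depression": eta[:, 0], "anxiety": eta[:, 1],
                         "z_dep": x[:, 0], "z_anx": x[:, 1], "stress": x[:, 2]})


LOOP_MODEL = SemModel(
    measurement={},
    regressions={"depression": ["anxiety", "z_dep", "stress"],
                 "anxiety": ["depression", "z_anx", "stress"]},
    psi="full",
)

LOOP_TRUTH = {"depression~anxiety": float(LOOP_B[0, 1]),
              "anxiety~depression": float(LOOP_B[1, 0]),
              "depression~z_dep": 0.6, "anxiety~z_anx": 0.5,
              "depression~stress": -0.06, "anxiety~stress": 0.54}


@dataclass
class CoverageResult:
    covered: dict[str, int]
    n_reps: int

    def rate(self, name: str) -> float:
        return self.covered[name] / self.n_reps


def coverage_study(n_reps: int = 100, n: int = 1000, n_boot: int = 200,
                   seed: int = 0,
                   parameters: tuple[str, ...] = ("depression~anxiety",
                                                  "anxiety~depression")) -> CoverageResult:
    """Bootstrap percentile-CI coverage of the loop coefficients."""
    covered = {p: 0 for p in parameters}
    rng = np.random.default_rng(seed)
    for r in range(n_reps):
        data = simulate_loop_observed(n, rng)
        fit = fit_sem(LOOP_MODEL, data)
        boot = bootstrap_fit(LOOP_MODEL, data, n_boot=n_boot,
                             seed=int(rng.integers(2**31 - 1)), fit=fit)
        for p in parameters:
            if boot.ci_low[p] <= LOOP_TRUTH[p] <= boot.ci_high[p]:
                covered[p] += 1
    return CoverageResult(covered=covered, n_reps=n_reps)
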