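"""Direct, indirect, and total effect decomposition through a feedback loop.

In a simultaneous system ``eta = B eta + Gamma xi + zeta`` the total effects
are

    T_endo = (I - B)^-1 - I          (endogenous on endogenous)
    T_exo  = (I - B)^-1 Gamma        (exogenous on endogenous)

equal to the sum of the path series ``B + B^2 + ...`` and
``Gamma + B Gamma + ...`` when the spectral radius of B is below one (the
loop converges).  Indirect = total - direct, so a variable in a reciprocal
loop can exert an "indirect" effect on its own partner through loop
amplification.  Confidence intervals come from applying the decomposition
to every bootstrap replicate (percentile method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem import BootstrapResult, FitResult, SemParameterSet


def total_effects(B: np.ndarray, Gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-effect matrices; errors out when the loop does not converge."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    Gamma = np.asarray(Gamma, dtype=float)
    m = B.shape[0]
    if m and np.max(np.abs(np.linalg.eigvals(B))) >= 1:
        raise ValueError("feedback loop non-convergent: spectral radius of B >= 1")
    A = np.linalg.inv(np.eye(m) - B)
    return A - np.eye(m), A @ Gamma


def _decompose(params: SemParameterSet) -> pd.DataFrame:
    m = params.m
    endo = params.latents[:m]
    exo = params.latents[m:]
    T_endo, T_exo = total_effects(params.beta, params.gamma)
    rows = []
    for i, out in enumerate(endo):
        for j, pred in enumerate(endo):
            if i == j:
                continue
            rows.append({"predictor": pred, "outcome": out,
                         "direct": params.beta[i, j],
                         "total": T_endo[i, j]})
        for j, pred in enumerate(exo):
            rows.append({"predictor": pred, "outcome": out,
                         "direct": params.gamma[i, j],
                         "total": T_exo[i, j]})
    tab = pd.DataFrame(rows)
    tab["indirect"] = tab["total"] - tab["direct"]
    return tab[["predictor", "outcome", "direct", "indirect", "total"]]


@dataclass
class EffectTable:
    table: pd.DataFrame
    standardized: bool = False
    ci_level: float | None = None

    def row(self, predictor: str, outcome: str) -> pd.Series:
        hit = self.table[(self.table.predictor == predictor) & (self.table.outcome == outcome)]
        if hit.empty:
            raise KeyError(f"no effect row for {predictor} -> {outcome}")
        return hit.iloc[0]


def _replicate_params(fit: FitResult, values: pd.Series) -> SemParameterSet:
    """Parameter set with a bootstrap replicate's free values substituted."""
    import copy
    p = copy.deepcopy(fit.params)
    p.unpack(values.to_numpy(float))
    return p


def effect_table(fit: FitResult, boot: BootstrapResult | None = None,
                 level: float = 0.95) -> EffectTable:
    """One row per (predictor, outcome): direct, indirect, total, with
    bootstrap percentile CIs per component when replicates are supplied."""
    point = _decompose(fit.params)
    if boot is None or boot.replicates.empty:
        point["ci_available"] = False
        return EffectTable(table=point, ci_level=None)
    reps = []
    for _, row in boot.replicates.iterrows():
        reps.append(_decompose(_replicate_params(fit, row))[["direct", "indirect", "total"]])
    stack = np.stack([r.to_numpy(float) for r in reps])  # n_rep x n_rows x 3
    a = (1 - level) / 2
    lo = np.quantile(stack, a, axis=0)
    hi = np.quantile(stack, 1 - a, axis=0)
    for c, name in enumerate(["direct", "indirect", "total"]):
        point[f"{name}_lo"] = lo[:, c]
        point[f"{name}_hi"] = hi[:, c]
    point["ci_available"] = True
    return EffectTable(table=point, ci_level=level)


def standardize_effects(table: EffectTable, variances: dict[str, float]) -> EffectTable:
    """Scale each effect by SD(predictor) / SD(outcome).

    ``variances`` maps variable names to model-implied variances; additivity
    (total = direct + indirect) is preserved because the transform is linear.
    """
    tab = table.table.copy()
    factors = []
    for _, r in tab.iterrows():
        v_out = variances[r["outcome"]]
        if v_out <= 0:
            raise ValueError(f"outcome {r['outcome']!r} has non-positive variance")
        factors.append(np.sqrt(variances[r["predictor"]] / v_out))
    f = np.asarray(factors)
    for col in tab.columns:
        if col.startswith(("direct", "indirect", "total")):
            tab[col] = tab[col].to_numpy(float) * f
    return EffectTable(table=tab, standardized=True, ci_level=table.ci_level)


def model_implied_latent_variances(fit: FitResult) -> dict[str, float]:
    """Variances of the latent constructs implied by the fitted system."""
    p = fit.params
    m = p.m
    A = np.linalg.inv(np.eye(m) - p.beta) if m else np.empty((0, 0))
    out: dict[str, float] = {}
    if m:
        C = p.gamma @ p.phi @ p.gamma.T + p.psi
        V = A @ C @ A.T
        for i, name in enumerate(p.latents[:m]):
            out[name] = float(V[i, i])
    for j, name in enumerate(p.latents[m:]):
        out[name] = float(p.phi[j, j])
    return out
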