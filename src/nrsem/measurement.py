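"""Confirmatory factor analysis and factorial item parceling.

CFA is a structural model with no regressions: every construct is exogenous
and only loadings, factor covariances and error variances are estimated.
Item parceling averages subsets of a construct's items into composite
indicators; the factorial (item-to-construct balance) assignment sorts
items by the magnitude of their single-factor loadings and deals them to
parcels in serpentine order so each parcel receives a comparable mix of
strong and weak items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem import FitResult, SemModel, fit_sem


def fit_cfa(measurement: dict[str, list[str]], data: pd.DataFrame,
            **kwargs) -> FitResult:
    """ML confirmatory factor analysis of the declared construct blocks."""
    for c, items in measurement.items():
        if len(items) < 2:
            raise ValueError(f"construct {c!r} needs >= 2 indicators for CFA")
    model = SemModel(measurement=measurement, regressions={})
    return fit_sem(model, data, **kwargs)


def single_factor_loadings(items: pd.DataFrame) -> pd.Series:
    """Standardized loadings of a one-factor model, via the first principal
    axis of the item correlation matrix (adequate for parcel ordering)."""
    X = items.to_numpy(float)
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    lam = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    if lam.sum() < 0:
        lam = -lam
    return pd.Series(lam, index=items.columns)


@dataclass(frozen=True)
class ParcelingPlan:
    """construct -> ordered parcels -> constituent items (a partition)."""

    assignment: dict[str, tuple[tuple[str, ...], ...]]

    def to_dict(self) -> dict:
        return {c: [list(p) for p in parcels] for c, parcels in self.assignment.items()}


def serpentine_assignment(loadings: pd.Series, k: int) -> tuple[tuple[str, ...], ...]:
    """Deal items (sorted by |loading| descending) to k parcels in serpentine
    order 1..k, k..1, 1..k, ...; ties broken by original item order."""
    if not (1 <= k <= len(loadings)):
        raise ValueError(f"parcel count {k} must be in [1, {len(loadings)}]")
    order = sorted(range(len(loadings)),
                   key=lambda i: (-abs(loadings.iloc[i]), i))
    positions: list[int] = []
    forward = True
    while len(positions) < len(order):
        positions.extend(range(k) if forward else range(k - 1, -1, -1))
        forward = not forward
    parcels: list[list[str]] = [[] for _ in range(k)]
    for rank, i in enumerate(order):
        parcels[positions[rank]].append(loadings.index[i])
    return tuple(tuple(p) for p in parcels)


def make_parcels(data: pd.DataFrame, construct_items: dict[str, list[str]],
                 k: int | dict[str, int] = 3,
                 loadings: dict[str, pd.Series] | None = None
                 ) -> tuple[ParcelingPlan, pd.DataFrame]:
    """Factorial parceling: balanced assignment + mean scoring.

    ``k`` is the parcel count (default 3; constructs with fewer than 6 items
    get 2).  Returns the plan and a frame of parcel scores named
    ``<construct>_p<j>``; a parcel score is the mean of its items.
    """
    assignment: dict[str, tuple[tuple[str, ...], ...]] = {}
    cols: dict[str, pd.Series] = {}
    for c, items in construct_items.items():
        if loadings is not None and c in loadings:
            lam = loadings[c].reindex(items)
        else:
            lam = single_factor_loadings(data[items].dropna())
        kc = k[c] if isinstance(k, dict) else (k if len(items) >= 6 else min(k, 2))
        kc = min(kc, len(items))
        if kc < 2 and len(items) > 1:
            raise ValueError(f"construct {c!r} needs >= 2 parcels to stay latent")
        parcels = serpentine_assignment(lam, kc)
        assignment[c] = parcels
        for j, parcel in enumerate(parcels, start=1):
            cols[f"{c}_p{j}"] = data[list(parcel)].mean(axis=1)
    return ParcelingPlan(assignment=assignment), pd.DataFrame(cols, index=data.index)


def parcel_measurement(plan: ParcelingPlan) -> dict[str, list[str]]:
    """Measurement map over parcel scores for downstream SEM fitting."""
    return {c: [f"{c}_p{j}" for j in range(1, len(parcels) + 1)]
            for c, parcels in plan.assignment.items()}
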