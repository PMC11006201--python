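"""Scoring and categorisation of the five screening instruments.

The study battery consists of PHQ-9A (adolescent depression), GAS-7/GAD-7
(generalised anxiety), SSS-8 (somatic symptom burden), PSS-10 (perceived
stress) and OSSS-3 (Oslo social support).  Each instrument is summed to a
total score; binary caseness flags and ordered severity bands follow the
published cutoffs.  Totals are left missing whenever any constituent item is
missing (no proration), which is conservative but unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


class ScaleValidationError(ValueError):
    """Raised when item responses fall outside the declared range."""


@dataclass(frozen=True)
class ScaleDefinition:
    """One questionnaire scale: items, per-item range, cutoff, severity bands.

    Parameters
    ----------
    name : str
        Scale identifier (e.g. ``"phq9a"``).
    items : tuple of str
        Column names of the constituent items, in instrument order.
    item_min, item_max : int
        Inclusive response range shared by every item.
    cutoff : int, optional
        Binary caseness threshold on the total score (flag is ``total >= cutoff``).
    bands : tuple of (label, lo, hi), optional
        Ordered, non-overlapping severity bands on the total score, inclusive.
    """

    name: str
    items: tuple[str, ...]
    item_min: int
    item_max: int
    cutoff: int | None = None
    bands: tuple[tuple[str, int, int], ...] = field(default=())
    item_maxes: tuple[int, ...] | None = None   # per-item maxima when unequal

    def __post_init__(self) -> None:
        lo, hi = self.total_range
        if self.cutoff is not None and not (lo <= self.cutoff <= hi):
            raise ValueError(f"{self.name}: cutoff {self.cutoff} outside total range [{lo}, {hi}]")
        prev_hi = None
        for label, b_lo, b_hi in self.bands:
            if b_lo > b_hi:
                raise ValueError(f"{self.name}: band {label!r} has lo > hi")
            if not (lo <= b_lo and b_hi <= hi):
                raise ValueError(f"{self.name}: band {label!r} outside total range [{lo}, {hi}]")
            if prev_hi is not None and b_lo <= prev_hi:
                raise ValueError(f"{self.name}: bands overlap or are unordered at {label!r}")
            prev_hi = b_hi

    @property
    def total_range(self) -> tuple[int, int]:
        k = len(self.items)
        hi = sum(self.item_maxes) if self.item_maxes else k * self.item_max
        return k * self.item_min, hi

    def item_max_for(self, col: str) -> int:
        if self.item_maxes is None:
            return self.item_max
        return self.item_maxes[self.items.index(col)]


def _items(prefix: str, k: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(1, k + 1))


#: The five instruments with their published scoring rules.  PHQ-9A and GAS-7
#: use caseness cutoffs of 10; SSS-8 and PSS-10 use ordered severity bands
#: (SSS-8 totals below the published low band are labelled "minimal");
#: OSSS-3 items are 1-based (first item 1-4, the others 1-5).
DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    "phq9a": ScaleDefinition(
        name="phq9a", items=_items("phq", 9), item_min=0, item_max=3, cutoff=10,
        bands=(("minimal", 0, 4), ("mild", 5, 9), ("moderate", 10, 14),
               ("moderately_severe", 15, 19), ("severe", 20, 27)),
    ),
    "gas7": ScaleDefinition(
        name="gas7", items=_items("gad", 7), item_min=0, item_max=3, cutoff=10,
        bands=(("minimal", 0, 4), ("mild", 5, 9), ("moderate", 10, 14), ("severe", 15, 21)),
    ),
    "sss8": ScaleDefinition(
        name="sss8", items=_items("sss", 8), item_min=0, item_max=4, cutoff=12,
        bands=(("minimal", 0, 3), ("low", 4, 7), ("medium", 8, 11),
               ("high", 12, 15), ("very_high", 16, 32)),
    ),
    "pss10": ScaleDefinition(
        name="pss10", items=_items("pss", 10), item_min=0, item_max=4, cutoff=None,
        bands=(("low", 0, 13), ("moderate", 14, 26), ("high", 27, 40)),
    ),
    "osss3": ScaleDefinition(
        name="osss3", items=_items("osss", 3), item_min=1, item_max=5, cutoff=None,
        bands=(("poor", 3, 8), ("moderate", 9, 11), ("strong", 12, 14)),
        item_maxes=(4, 5, 5),   # first item runs 1-4, the other two 1-5
    ),
}


def _validate_items(responses: pd.DataFrame, scale: ScaleDefinition) -> None:
    missing_cols = [c for c in scale.items if c not in responses.columns]
    if missing_cols:
        raise ScaleValidationError(f"{scale.name}: item columns absent: {missing_cols}")
    bad: list[str] = []
    for col in scale.items:
        hi = scale.item_max_for(col)
        vals = responses[col]
        out = vals.notna() & ((vals < scale.item_min) | (vals > hi))
        if out.any():
            rows = list(responses.index[out][:5])
            bad.append(f"{col} rows {rows}")
    if bad:
        raise ScaleValidationError(f"{scale.name}: out-of-range responses: {'; '.join(bad)}")


def score_scale(responses: pd.DataFrame, scale: ScaleDefinition) -> pd.Series:
    """Sum the scale's items; missing if any constituent item is missing."""
    _validate_items(responses, scale)
    block = responses[list(scale.items)]
    totals = block.sum(axis=1, min_count=len(scale.items))
    return totals.rename(f"{scale.name}_total")


def classify(totals: pd.Series, scale: ScaleDefinition) -> pd.DataFrame:
    """Binary flag (total >= cutoff) and severity band for each record.

    Totals falling outside every declared band are labelled ``"unbanded"``
    rather than silently dropped.
    """
    out = pd.DataFrame(index=totals.index)
    if scale.cutoff is not None:
        flag = pd.Series(pd.NA, index=totals.index, dtype="boolean")
        ok = totals.notna()
        flag[ok] = totals[ok] >= scale.cutoff
        out[f"{scale.name}_flag"] = flag
    if scale.bands:
        band = pd.Series(pd.NA, index=totals.index, dtype="object")
        unmatched = totals.notna()
        for label, lo, hi in scale.bands:
            in_band = totals.notna() & (totals >= lo) & (totals <= hi)
            band[in_band] = label
            unmatched &= ~in_band
        band[unmatched] = "unbanded"
        out[f"{scale.name}_band"] = band
    return out


@dataclass(frozen=True)
class Prevalence:
    proportion: float
    ci_low: float
    ci_high: float
    n: int
    n_positive: int
    method: str

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


def prevalence(flags: pd.Series, method: str = "wilson", alpha: float = 0.05) -> Prevalence:
    """Proportion flagged positive with a 95% CI (Wilson score by default).

    ``method`` is passed to :func:`statsmodels.stats.proportion.proportion_confint`
    (``"wilson"`` or ``"beta"`` for exact Clopper-Pearson).
    """
    valid = flags.dropna()
    n = int(valid.shape[0])
    if n == 0:
        raise ValueError("prevalence undefined: no non-missing flags")
    k = int(valid.astype(bool).sum())
    lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
    return Prevalence(proportion=k / n, ci_low=float(lo), ci_high=float(hi),
                      n=n, n_positive=k, method=method)


def apply_listwise(dataset: pd.DataFrame, max_fraction: float = 0.05,
                   columns: list[str] | None = None) -> pd.DataFrame:
    """Drop records with any missing analysis variable, refusing above a cap.

    Listwise deletion is only defensible when the incomplete fraction is
    small; if it exceeds ``max_fraction`` the call refuses and reports the
    attained fraction so the caller can choose another missing-data strategy.
    """
    if not (0 < max_fraction <= 0.5):
        raise ValueError("max_fraction must be in (0, 0.5]")
    cols = columns if columns is not None else list(dataset.columns)
    incomplete = dataset[cols].isna().any(axis=1)
    frac = float(incomplete.mean())
    if frac > max_fraction:
        raise ValueError(
            f"listwise deletion refused: {frac:.1%} of records incomplete exceeds the "
            f"{max_fraction:.0%} cap; consider imputation or FIML instead"
        )
    return dataset.loc[~incomplete].copy()


def score_dataset(data: pd.DataFrame,
                  scales: dict[str, ScaleDefinition] | None = None) -> pd.DataFrame:
    """Totals, flags and bands for every scale, appended to a copy of ``data``."""
    scales = scales or DEFAULT_SCALES
    out = data.copy()
    for sc in scales.values():
        totals = score_scale(data, sc)
        out[totals.name] = totals
        cls = classify(totals, sc)
        for col in cls.columns:
            out[col] = cls[col]
    return out


def prevalence_report(scored: pd.DataFrame,
                      scales: dict[str, ScaleDefinition] | None = None,
                      method: str = "wilson") -> dict[str, dict]:
    """JSON-ready prevalence summary for every scale with a caseness cutoff."""
    scales = scales or DEFAULT_SCALES
    report: dict[str, dict] = {}
    for name, sc in scales.items():
        if sc.cutoff is None:
            continue
        prev = prevalence(scored[f"{name}_flag"], method=method)
        report[name] = {
            "percent": prev.percent,
            "ci_low_percent": 100 * prev.ci_low,
            "ci_high_percent": 100 * prev.ci_high,
            "n": prev.n,
            "n_positive": prev.n_positive,
            "cutoff": sc.cutoff,
            "ci_method": prev.method,
        }
    return report
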