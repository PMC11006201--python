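"""Pre-model data screening: multivariate normality, outliers, sampling
adequacy, clustering, and common-method bias.

Every statistic follows its textbook definition; the verdict thresholds are
the conventional ones used in applied SEM (Mardia kurtosis > 7 with critical
ratio > 5 -> non-normal; Mahalanobis chi-square p < 0.001 -> outlier; KMO >
0.7 adequate; ICC < 0.1 -> classical SEM acceptable; first-factor share <
50% -> no common-method bias).  Sample covariances use the n-1 denominator
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _clean_matrix(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D table")
    if np.isnan(X).any():
        raise ValueError("missing values present; apply listwise deletion first")
    return X


def _inv_cov(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    # pinpoint collinear columns before failing
    if np.linalg.matrix_rank(S) < S.shape[0]:
        corr = np.corrcoef(X, rowvar=False)
        dup = [(i, j) for i in range(S.shape[0]) for j in range(i)
               if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError(f"singular covariance matrix; near-duplicate column pairs: {dup}")
    return S, np.linalg.inv(S)


# ---------------------------------------------------------------------------
# Multivariate normality (Mardia's kurtosis)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityReport:
    b2p: float                 # Mardia multivariate kurtosis
    expected: float            # p(p+2) under multivariate normality
    critical_ratio: float
    p_variables: int
    n: int
    nonnormal: bool            # kurtosis > 7 above expectation rule + CR rule


def mardia_kurtosis(data: pd.DataFrame | np.ndarray,
                    kurtosis_threshold: float = 7.0,
                    cr_threshold: float = 5.0) -> NormalityReport:
    """Mardia's multivariate kurtosis b2p and its critical ratio.

    b2p is the mean of squared Mahalanobis distances; under multivariate
    normality E[b2p] = p(p+2) and CR = (b2p - p(p+2)) / sqrt(8 p (p+2) / n)
    is asymptotically standard normal.  The screening verdict flags
    non-normality when the kurtosis excess exceeds ``kurtosis_threshold``
    and the critical ratio exceeds ``cr_threshold``.
    """
    X = _clean_matrix(data)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    _, Sinv = _inv_cov(X)
    D = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", D, Sinv, D)
    b2p = float(np.mean(d2 ** 2))
    expected = p * (p + 2)
    cr = (b2p - expected) / np.sqrt(8 * p * (p + 2) / n)
    nonnormal = (b2p - expected > kurtosis_threshold) and (cr > cr_threshold)
    return NormalityReport(b2p=b2p, expected=float(expected), critical_ratio=float(cr),
                           p_variables=p, n=n, nonnormal=bool(nonnormal))


# ---------------------------------------------------------------------------
# Multivariate outliers (Mahalanobis distance)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierReport:
    d2: np.ndarray             # squared Mahalanobis distance per record
    p_values: np.ndarray       # chi-square upper tail, df = p
    flags: np.ndarray          # p < alpha
    alpha: float
    df: int

    @property
    def n_outliers(self) -> int:
        return int(self.flags.sum())


def mahalanobis_outliers(data: pd.DataFrame | np.ndarray,
                         alpha: float = 0.001) -> OutlierReport:
    """Flag records whose squared Mahalanobis distance is extreme under the
    chi-square(p) reference distribution."""
    X = _clean_matrix(data)
    n, p = X.shape
    _, Sinv = _inv_cov(X)
    D = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", D, Sinv, D)
    pvals = stats.chi2.sf(d2, df=p)
    return OutlierReport(d2=d2, p_values=pvals, flags=pvals < alpha, alpha=alpha, df=p)


# ---------------------------------------------------------------------------
# Sampling adequacy (KMO and Bartlett)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmoReport:
    overall: float
    per_variable: np.ndarray


def kmo(data: pd.DataFrame | np.ndarray, is_correlation: bool = False) -> KmoReport:
    """Kaiser-Meyer-Olkin sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    partial correlations obtained from the inverted correlation matrix.
    For p = 2 the partial correlation equals the marginal one, so KMO = 0.5
    exactly whatever the data.
    """
    if is_correlation:
        R = np.asarray(data, dtype=float)
    else:
        X = _clean_matrix(data)
        if X.shape[1] < 2:
            raise ValueError("KMO needs at least two variables")
        R = np.corrcoef(X, rowvar=False)
    p = R.shape[0]
    if np.linalg.matrix_rank(R) < p:
        raise ValueError("correlation matrix is singular; KMO undefined")
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d  # partial correlations (off-diagonal)
    off = ~np.eye(p, dtype=bool)
    r2 = R[off] ** 2
    q2 = Q[off] ** 2
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    per_var = np.array([
        (R[i, off[i]] ** 2).sum() / ((R[i, off[i]] ** 2).sum() + (Q[i, off[i]] ** 2).sum())
        for i in range(p)
    ])
    return KmoReport(overall=overall, per_variable=per_var)


@dataclass(frozen=True)
class BartlettResult:
    chi2: float
    df: int
    p_value: float


def bartlett_sphericity(R: np.ndarray, n: int) -> BartlettResult:
    """Bartlett's test of sphericity on a correlation matrix.

    chi2 = -(n - 1 - (2p + 5)/6) ln|R|, df = p(p-1)/2.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix must have positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = max(float(chi2), 0.0)
    df = p * (p - 1) // 2
    return BartlettResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def adequacy_report(data: pd.DataFrame, constructs: dict[str, list[str]]) -> dict:
    """KMO + Bartlett per construct and overall, JSON-ready (Table-3 layout)."""
    out: dict[str, dict] = {}
    all_items: list[str] = []
    for name, items in constructs.items():
        all_items.extend(items)
        block = data[items].dropna()
        rep = kmo(block)
        bart = bartlett_sphericity(np.corrcoef(block.to_numpy(float), rowvar=False),
                                   block.shape[0])
        out[name] = {"kmo": rep.overall, "bartlett_chi2": bart.chi2,
                     "bartlett_df": bart.df, "bartlett_p": bart.p_value}
    block = data[all_items].dropna()
    rep = kmo(block)
    bart = bartlett_sphericity(np.corrcoef(block.to_numpy(float), rowvar=False),
                               block.shape[0])
    out["overall"] = {"kmo": rep.overall, "bartlett_chi2": bart.chi2,
                      "bartlett_df": bart.df, "bartlett_p": bart.p_value}
    return out


# ---------------------------------------------------------------------------
# Independence of observations (one-way ANOVA ICC)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IccResult:
    icc: float
    msb: float
    msw: float
    n_clusters: int
    n: int


def icc(values: pd.Series | np.ndarray, clusters: pd.Series | np.ndarray) -> IccResult:
    """ICC(1) from a one-way random-effects ANOVA, unbalanced-design form.

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW) with k0 the average cluster
    size adjusted for imbalance: k0 = (N - sum n_j^2 / N) / (J - 1).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(clusters)
    ok = ~np.isnan(y)
    y, g = y[ok], g[ok]
    labels, inverse = np.unique(g, return_inverse=True)
    J = len(labels)
    if J < 2:
        raise ValueError("ICC needs at least two clusters")
    N = len(y)
    nj = np.bincount(inverse)
    means = np.bincount(inverse, weights=y) / nj
    grand = y.mean()
    ssb = float(np.sum(nj * (means - grand) ** 2))
    ssw = float(np.sum((y - means[inverse]) ** 2))
    msb = ssb / (J - 1)
    msw = ssw / (N - J)
    k0 = (N - np.sum(nj ** 2) / N) / (J - 1)
    val = (msb - msw) / (msb + (k0 - 1) * msw)
    return IccResult(icc=float(val), msb=msb, msw=msw, n_clusters=J, n=N)


@dataclass(frozen=True)
class ClusteringReport:
    iccs: dict[str, dict[str, float]]   # cluster variable -> outcome -> ICC
    threshold: float
    independent: bool                   # all ICC < threshold


def clustering_report(data: pd.DataFrame, outcomes: list[str],
                      cluster_vars: list[str], threshold: float = 0.1) -> ClusteringReport:
    iccs: dict[str, dict[str, float]] = {}
    for cv in cluster_vars:
        iccs[cv] = {out: icc(data[out], data[cv]).icc for out in outcomes}
    ok = all(v < threshold for d in iccs.values() for v in d.values())
    return ClusteringReport(iccs=iccs, threshold=threshold, independent=ok)


# ---------------------------------------------------------------------------
# Common method bias (Harman's one-factor test)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CmbReport:
    first_factor_share: float
    threshold: float
    cmb_suspected: bool
    method: str


def harman_single_factor(items: pd.DataFrame | np.ndarray, threshold: float = 0.5,
                         method: str = "pca") -> CmbReport:
    """Share of total variance captured by a single factor over all items.

    ``method="pca"`` (default) uses the first eigenvalue of the item
    correlation matrix divided by the number of items; ``method="paf"``
    iterates communalities (principal-axis) before extracting.
    """
    X = _clean_matrix(items)
    if X.shape[1] < 3:
        raise ValueError("need at least three items")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant item columns present")
    R = np.corrcoef(X, rowvar=False)
    p = R.shape[0]
    if method == "pca":
        share = float(np.linalg.eigvalsh(R)[-1] / p)
    elif method == "paf":
        Rw = R.copy()
        comm = 1 - 1 / np.diag(np.linalg.inv(R))  # SMC initial communalities
        for _ in range(50):
            np.fill_diagonal(Rw, comm)
            evals, evecs = np.linalg.eigh(Rw)
            lam = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
            new_comm = lam ** 2
            if np.max(np.abs(new_comm - comm)) < 1e-6:
                comm = new_comm
                break
            comm = new_comm
        share = float(np.sum(lam ** 2) / p)
    else:
        raise ValueError("method must be 'pca' or 'paf'")
    return CmbReport(first_factor_share=share, threshold=threshold,
                     cmb_suspected=share >= threshold, method=method)
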