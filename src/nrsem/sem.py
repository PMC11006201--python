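"""Maximum-likelihood estimation of non-recursive latent structural models.

Model form (LISREL-style, all observed variables collected in one vector):

    structural   eta = B eta + Gamma xi + zeta,   zeta ~ N(0, Psi)
    measurement  v   = Lambda (eta, xi) + eps,    eps  ~ N(0, Theta)

with exogenous covariance ``Phi = Cov(xi)``.  ``B`` may contain reciprocal
entries (a feedback loop such as depression <-> anxiety); the model is
evaluable wherever ``I - B`` is invertible.  Observed variables that enter
the structural part directly (binary covariates, composite scores) are
handled as single-indicator constructs with loading fixed at 1 and zero
measurement error.

Estimation minimises the Wishart ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

by quasi-Newton iterations with an analytic gradient; ``chi2 = (n-1) F`` at
the minimum.  Inference mirrors applied practice for non-normal Likert
data: ML point estimates with bootstrap percentile confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


class SemError(RuntimeError):
    pass


class HeywoodWarning(UserWarning):
    """Negative estimated error variance (improper solution)."""


# ---------------------------------------------------------------------------
# Model declaration
# ---------------------------------------------------------------------------

@dataclass
class SemModel:
    """Declarative model: measurement blocks plus structural regressions.

    Parameters
    ----------
    measurement : dict
        Construct -> list of observed indicator columns.  Constructs with a
        single indicator get loading 1 and zero measurement error (exact
        proxies); multi-indicator constructs fix the first loading at 1 for
        scale-setting and free the rest.
    regressions : dict
        Endogenous construct -> list of predictor constructs.  Predictors
        that are plain observed columns are promoted to single-indicator
        constructs automatically.
    psi : "full" | "diag" | list of (a, b)
        Which disturbance covariances to free besides the diagonal.
        ``"full"`` frees every pair (complete correlation of error terms).
    """

    measurement: dict[str, list[str]]
    regressions: dict[str, list[str]] = field(default_factory=dict)
    psi: str | list[tuple[str, str]] = "full"

    def __post_init__(self) -> None:
        meas = {k: list(v) for k, v in self.measurement.items()}
        mentioned = set(self.regressions) | {p for ps in self.regressions.values() for p in ps}
        for name in mentioned:
            if name not in meas:
                meas[name] = [name]  # observed variable as its own construct
        self.measurement = meas
        for out, preds in self.regressions.items():
            if out in preds:
                raise SemError(f"{out!r} regresses on itself")
        seen: set[str] = set()
        for c, items in meas.items():
            for it in items:
                if it in seen:
                    raise SemError(f"indicator {it!r} loads on more than one construct")
                seen.add(it)

    @property
    def endogenous(self) -> list[str]:
        return list(self.regressions)

    @property
    def exogenous(self) -> list[str]:
        return [c for c in self.measurement if c not in self.regressions]

    @property
    def latents(self) -> list[str]:
        return self.endogenous + self.exogenous

    @property
    def observed(self) -> list[str]:
        return [it for c in self.latents for it in self.measurement[c]]


@dataclass
class SemParameterSet:
    """Matrix parameterisation with free/fixed masks (True = free)."""

    lam: np.ndarray          # p x t loadings (t = m + k latents)
    beta: np.ndarray         # m x m endogenous -> endogenous
    gamma: np.ndarray        # m x k exogenous -> endogenous
    phi: np.ndarray          # k x k exogenous covariance
    psi: np.ndarray          # m x m disturbance covariance
    theta: np.ndarray        # p-vector measurement error variances
    lam_free: np.ndarray
    beta_free: np.ndarray
    gamma_free: np.ndarray
    phi_free: np.ndarray     # upper triangle incl diagonal
    psi_free: np.ndarray
    theta_free: np.ndarray
    observed: list[str]
    latents: list[str]
    m: int                   # number of endogenous latents

    # -- free-vector packing ------------------------------------------------
    def _free_indices(self):
        cached = getattr(self, "_free_idx_cache", None)
        if cached is not None:
            return cached
        m = self.m
        idx = []
        for i, j in zip(*np.where(self.lam_free)):
            idx.append(("lam", i, j))
        for i, j in zip(*np.where(self.beta_free)):
            idx.append(("beta", i, j))
        for i, j in zip(*np.where(self.gamma_free)):
            idx.append(("gamma", i, j))
        k = self.phi.shape[0]
        for i in range(k):
            for j in range(i, k):
                if self.phi_free[i, j]:
                    idx.append(("phi", i, j))
        for i in range(m):
            for j in range(i, m):
                if self.psi_free[i, j]:
                    idx.append(("psi", i, j))
        for (i,) in zip(*np.where(self.theta_free)):
            idx.append(("theta", i, i))
        object.__setattr__(self, "_free_idx_cache", idx)
        return idx

    @property
    def q(self) -> int:
        return len(self._free_indices())

    def pack(self) -> np.ndarray:
        vals = []
        for mat, i, j in self._free_indices():
            vals.append(self.theta[i] if mat == "theta" else getattr(self, mat)[i, j])
        return np.array(vals, dtype=float)

    def unpack(self, vec: np.ndarray) -> None:
        for v, (mat, i, j) in zip(vec, self._free_indices()):
            if mat == "theta":
                self.theta[i] = v
            else:
                M = getattr(self, mat)
                M[i, j] = v
                if mat in ("phi", "psi") and i != j:
                    M[j, i] = v

    def parameter_names(self) -> list[str]:
        names = []
        for mat, i, j in self._free_indices():
            if mat == "lam":
                names.append(f"{self.latents[j]}=~{self.observed[i]}")
            elif mat == "beta":
                names.append(f"{self.latents[i]}~{self.latents[j]}")
            elif mat == "gamma":
                names.append(f"{self.latents[i]}~{self.latents[self.m + j]}")
            elif mat == "phi":
                names.append(f"phi[{self.latents[self.m + i]},{self.latents[self.m + j]}]")
            elif mat == "psi":
                names.append(f"psi[{self.latents[i]},{self.latents[j]}]")
            else:
                names.append(f"theta[{self.observed[i]}]")
        return names


def build_parameters(model: SemModel, data: pd.DataFrame) -> SemParameterSet:
    """Masks and moment-based start values for a declared model."""
    endo, exo = model.endogenous, model.exogenous
    latents = model.latents
    observed = model.observed
    m, k, t, p = len(endo), len(exo), len(latents), len(observed)
    obs_ix = {v: i for i, v in enumerate(observed)}
    lat_ix = {v: i for i, v in enumerate(latents)}

    lam = np.zeros((p, t))
    lam_free = np.zeros((p, t), dtype=bool)
    theta = np.zeros(p)
    theta_free = np.zeros(p, dtype=bool)
    for c in latents:
        items = model.measurement[c]
        j = lat_ix[c]
        for r, it in enumerate(items):
            i = obs_ix[it]
            if r == 0:
                lam[i, j] = 1.0                       # scale-setting marker
            else:
                lam[i, j] = 0.7
                lam_free[i, j] = True
            if len(items) > 1:
                theta[i] = 0.5 * float(np.var(data[it], ddof=1))
                theta_free[i] = True
            # single-indicator constructs keep theta = 0 fixed

    beta = np.zeros((m, m))
    beta_free = np.zeros((m, m), dtype=bool)
    gamma = np.zeros((m, k))
    gamma_free = np.zeros((m, k), dtype=bool)
    for out, preds in model.regressions.items():
        i = lat_ix[out]
        for pvar in preds:
            j = lat_ix[pvar]
            if pvar in model.regressions:
                beta_free[i, j] = True
            else:
                gamma_free[i, j - m] = True

    # proxy composites give PD start values for phi / psi
    proxies = np.column_stack([
        data[model.measurement[c]].mean(axis=1).to_numpy(float) for c in latents
    ]) if t else np.empty((len(data), 0))
    proxy_cov = np.cov(proxies, rowvar=False, ddof=1) if t else np.empty((0, 0))
    proxy_cov = np.atleast_2d(proxy_cov)

    phi = proxy_cov[m:, m:].copy() if k else np.empty((0, 0))
    phi_free = np.ones((k, k), dtype=bool)
    psi = np.diag(0.5 * np.diag(proxy_cov)[:m]) if m else np.empty((0, 0))
    psi_free = np.eye(m, dtype=bool)
    if model.psi == "full":
        psi_free[:] = True
    elif model.psi == "diag":
        pass
    else:
        for a, b in model.psi:
            ia, ib = lat_ix[a], lat_ix[b]
            psi_free[ia, ib] = psi_free[ib, ia] = True

    return SemParameterSet(
        lam=lam, beta=beta, gamma=gamma, phi=phi, psi=psi, theta=theta,
        lam_free=lam_free, beta_free=beta_free, gamma_free=gamma_free,
        phi_free=phi_free, psi_free=psi_free, theta_free=theta_free,
        observed=observed, latents=latents, m=m,
    )


# ---------------------------------------------------------------------------
# Implied covariance and discrepancy
# ---------------------------------------------------------------------------

def implied_covariance(params: SemParameterSet) -> np.ndarray:
    """Sigma(theta) = Lambda Omega Lambda' + Theta with

    Omega = [[A C A', A Gamma Phi], [Phi Gamma' A', Phi]],
    A = (I - B)^-1, C = Gamma Phi Gamma' + Psi.
    """
    m = params.m
    t = params.lam.shape[1]
    ImB = np.eye(m) - params.beta
    if m and abs(np.linalg.det(ImB)) < 1e-12:
        raise SemError("(I - B) is singular at the evaluated point (degenerate loop)")
    A = np.linalg.inv(ImB) if m else np.empty((0, 0))
    Omega = np.zeros((t, t))
    if m:
        C = params.gamma @ params.phi @ params.gamma.T + params.psi
        Omega[:m, :m] = A @ C @ A.T
        if t > m:
            AGP = A @ params.gamma @ params.phi
            Omega[:m, m:] = AGP
            Omega[m:, :m] = AGP.T
    if t > m:
        Omega[m:, m:] = params.phi
    Sigma = params.lam @ Omega @ params.lam.T + np.diag(params.theta)
    return (Sigma + Sigma.T) / 2


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray, n: int) -> tuple[float, float]:
    """Wishart ML fit function and its chi-square: F >= 0 with F = 0 iff Sigma = S."""
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise SemError("S and Sigma must be positive definite")
    F = logdet_m + float(np.trace(S @ np.linalg.inv(Sigma))) - logdet_s - p
    F = max(F, 0.0)
    return F, (n - 1) * F


# ---------------------------------------------------------------------------
# Objective with analytic gradient
# ---------------------------------------------------------------------------

_BIG = 1e10


def _objective(vec: np.ndarray, params: SemParameterSet, S: np.ndarray):
    params.unpack(vec)
    m = params.m
    t = params.lam.shape[1]
    ImB = np.eye(m) - params.beta
    if m and abs(np.linalg.det(ImB)) < 1e-10:
        return _BIG, np.zeros_like(vec)
    A = np.linalg.inv(ImB) if m else np.empty((0, 0))
    Omega = np.zeros((t, t))
    if m:
        C = params.gamma @ params.phi @ params.gamma.T + params.psi
        Omega[:m, :m] = A @ C @ A.T
        if t > m:
            AGP = A @ params.gamma @ params.phi
            Omega[:m, m:] = AGP
            Omega[m:, :m] = AGP.T
    if t > m:
        Omega[m:, m:] = params.phi
    Sigma = params.lam @ Omega @ params.lam.T + np.diag(params.theta)
    Sigma = (Sigma + Sigma.T) / 2
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return _BIG, np.zeros_like(vec)
    p = S.shape[0]
    logdet_m = 2 * float(np.sum(np.log(np.diag(L))))
    Sinv_S = np.linalg.solve(Sigma, S)  # Sigma^-1 S  (via cholesky-backed solve)
    sign_s, logdet_s = np.linalg.slogdet(S)
    F = logdet_m + float(np.trace(Sinv_S)) - logdet_s - p

    Sigma_inv = np.linalg.inv(Sigma)
    W = Sigma_inv - Sigma_inv @ S @ Sigma_inv   # dF/dSigma
    # chain rule through the blocks
    G_lam = 2 * W @ params.lam @ Omega
    M = params.lam.T @ W @ params.lam
    M11 = M[:m, :m]
    M12 = M[:m, m:]
    M22 = M[m:, m:]
    if m:
        AtM11A = A.T @ M11 @ A
        G_psi = AtM11A
        AG = A @ params.gamma
        G_phi = AG.T @ M11 @ AG + AG.T @ M12 + (AG.T @ M12).T + M22
        G_gamma = 2 * AtM11A @ params.gamma @ params.phi + 2 * A.T @ M12 @ params.phi
        Omega11 = Omega[:m, :m]
        Omega12 = Omega[:m, m:]
        G_beta = 2 * A.T @ M11 @ Omega11 + 2 * A.T @ M12 @ Omega12.T
    else:
        G_phi = M22
        G_psi = G_gamma = G_beta = None

    grad = np.empty_like(vec)
    for ix, (mat, i, j) in enumerate(params._free_indices()):
        if mat == "lam":
            grad[ix] = G_lam[i, j]
        elif mat == "beta":
            grad[ix] = G_beta[i, j]
        elif mat == "gamma":
            grad[ix] = G_gamma[i, j]
        elif mat == "phi":
            grad[ix] = G_phi[i, j] + G_phi[j, i] if i != j else G_phi[i, i]
        elif mat == "psi":
            grad[ix] = G_psi[i, j] + G_psi[j, i] if i != j else G_psi[i, i]
        else:
            grad[ix] = W[i, i]
    return F, grad


# ---------------------------------------------------------------------------
# Fit results and indices
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    estimates: dict[str, float]
    se: dict[str, float]
    loglik: float
    chi2: float
    df: int
    cmin_df: float | None
    cfi: float
    tli: float | None
    rmsea: float | None
    aic: float
    n: int
    q: int
    converged: bool
    n_iter: int
    grad_norm: float
    params: SemParameterSet
    model: SemModel
    baseline_chi2: float
    baseline_df: int

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates, "se": self.se, "chi2": self.chi2,
            "df": self.df, "cmin_df": self.cmin_df, "cfi": self.cfi,
            "tli": self.tli, "rmsea": self.rmsea, "aic": self.aic,
            "n": self.n, "q": self.q, "converged": self.converged,
            "loglik": self.loglik,
        }


def fit_indices(chi2: float, df: int, baseline_chi2: float, baseline_df: int,
                n: int, q: int) -> dict:
    """CFI, TLI, RMSEA, AIC, CMIN/DF from chi-squares of the fitted and the
    independence (baseline) model."""
    num = max(chi2 - df, 0.0)
    denom = max(baseline_chi2 - baseline_df, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    if df > 0 and baseline_df > 0 and baseline_chi2 / baseline_df != 1:
        tli = (baseline_chi2 / baseline_df - chi2 / df) / (baseline_chi2 / baseline_df - 1)
    else:
        tli = None
    rmsea = float(np.sqrt(num / (df * (n - 1)))) if df > 0 else None
    return {
        "cfi": float(cfi), "tli": None if tli is None else float(tli),
        "rmsea": rmsea, "aic": float(chi2 + 2 * q),
        "cmin_df": None if df == 0 else float(chi2 / df),
    }


def _baseline_chi2(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence model (diagonal Sigma, free variances): closed-form ML."""
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)
    F = float(np.sum(np.log(np.diag(S))) - logdet_s)
    return (n - 1) * F, p * (p - 1) // 2


def _numeric_hessian(x: np.ndarray, params: SemParameterSet, S: np.ndarray,
                     h: float = 1e-5) -> np.ndarray:
    q = len(x)
    H = np.zeros((q, q))
    for j in range(q):
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        _, gp = _objective(xp, params, S)
        _, gm = _objective(xm, params, S)
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def _newton_polish(x: np.ndarray, params: SemParameterSet, S: np.ndarray,
                   gtol: float = 1e-6, max_steps: int = 15):
    """Damped Newton refinement; rescues quasi-Newton runs that stall on
    flat, ill-conditioned likelihood surfaces."""
    f, g = _objective(x, params, S)
    for _ in range(max_steps):
        if np.linalg.norm(g, np.inf) < gtol or f >= _BIG / 2:
            break
        H = _numeric_hessian(x, params, S)
        lam = 1e-8
        for _ in range(12):
            try:
                step = np.linalg.solve(H + lam * np.eye(len(x)), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            f_new, g_new = _objective(x + step, params, S)
            if f_new <= f + 1e-14:
                x, f, g = x + step, f_new, g_new
                break
            lam *= 10
        else:
            break
    return x, f, g


def fit_sem(model: SemModel, data: pd.DataFrame, max_iter: int = 2000,
            gtol: float = 1e-7, n_restarts: int = 3,
            start: np.ndarray | None = None) -> FitResult:
    """Estimate the model on complete-case data by quasi-Newton ML.

    Raises on non-convergence after damped restarts; warns (``HeywoodWarning``)
    when an error variance goes negative.
    """
    cols = model.observed
    block = data[cols]
    if block.isna().any().any():
        raise SemError("missing values in model variables; apply listwise deletion first")
    X = block.to_numpy(float)
    n, p = X.shape
    S = np.cov(X, rowvar=False, ddof=1)
    params = build_parameters(model, data)
    q = params.q
    df = p * (p + 1) // 2 - q
    if df < 0:
        raise SemError(f"model not identified: q={q} exceeds moments {p*(p+1)//2}")
    if n <= q:
        raise SemError(f"too few observations (n={n}) for q={q} free parameters")

    x_init = params.pack() if start is None else np.asarray(start, dtype=float)
    rng = np.random.default_rng(0)
    best = None
    x0 = x_init
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(_objective, x0, args=(params, S), jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": max_iter, "gtol": gtol,
                                         "ftol": 1e-12, "maxcor": 30})
        if best is None or res.fun < best.fun:
            best = res
        if res.fun < _BIG / 2 and np.linalg.norm(res.jac, np.inf) < 1e-3:
            break
        # damped restart: jitter around the moment-based start values
        x0 = x_init + rng.normal(0, 0.05, size=q)
    res = best
    if res.fun >= _BIG / 2:
        raise SemError("optimizer stuck in an infeasible region (singular loop or non-PD "
                       "covariance); revise the model or start values")
    x_opt, f_opt, g_opt = _newton_polish(res.x, params, S)
    res.x, res.fun, res.jac = x_opt, f_opt, g_opt
    params.unpack(res.x)
    converged = bool(res.fun < _BIG / 2 and np.linalg.norm(res.jac, np.inf) < 1e-3)

    neg = [params.observed[i] for i in np.where(params.theta_free & (params.theta < 0))[0]]
    for i in range(params.m):
        if params.psi[i, i] < 0:
            neg.append(f"psi[{params.latents[i]}]")
    if neg:
        warnings.warn(f"Heywood case: negative error variance for {neg}",
                      HeywoodWarning, stacklevel=2)

    F = float(res.fun)
    chi2 = (n - 1) * F
    chi2_b, df_b = _baseline_chi2(S, n)
    idx = fit_indices(chi2, df, chi2_b, df_b, n, q)
    # Gaussian log-likelihood at the optimum
    Sigma = implied_covariance(params)
    sign, logdet = np.linalg.slogdet(Sigma)
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + logdet
                         + float(np.trace(np.linalg.solve(Sigma, S))) * (n - 1) / n)

    se = _standard_errors(params, S, n, res.x)
    names = params.parameter_names()
    return FitResult(
        estimates=dict(zip(names, [float(v) for v in res.x])),
        se=se, loglik=float(loglik), chi2=float(chi2), df=int(df),
        cmin_df=idx["cmin_df"], cfi=idx["cfi"], tli=idx["tli"],
        rmsea=idx["rmsea"], aic=idx["aic"], n=n, q=q,
        converged=converged, n_iter=int(res.nit),
        grad_norm=float(np.linalg.norm(res.jac, np.inf)),
        params=params, model=model, baseline_chi2=float(chi2_b), baseline_df=int(df_b),
    )


def _standard_errors(params: SemParameterSet, S: np.ndarray, n: int,
                     xopt: np.ndarray) -> dict[str, float]:
    """Observed-information SEs: acov = (2/(n-1)) H^-1 with H the numerical
    Hessian of F (central differences of the analytic gradient)."""
    q = len(xopt)
    H = np.zeros((q, q))
    h = 1e-5
    for j in range(q):
        xp = xopt.copy(); xp[j] += h
        xm = xopt.copy(); xm[j] -= h
        _, gp = _objective(xp, params, S)
        _, gm = _objective(xm, params, S)
        H[:, j] = (gp - gm) / (2 * h)
    params.unpack(xopt)  # restore
    H = (H + H.T) / 2
    try:
        acov = 2.0 / (n - 1) * np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(acov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(q, np.nan)
    return dict(zip(params.parameter_names(), [float(s) for s in ses]))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    replicates: pd.DataFrame        # one row per successful replicate
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_requested: int
    n_failed: int
    seed: int
    level: float


def bootstrap_fit(model: SemModel, data: pd.DataFrame, n_boot: int = 3000,
                  seed: int = 0, level: float = 0.95,
                  max_failure_rate: float = 0.2,
                  fit: FitResult | None = None) -> BootstrapResult:
    """Case-resampling bootstrap: refit on resampled rows, percentile CIs.

    Replicates start from the full-data solution for speed; failed refits
    are logged and excluded, and an error is raised when more than
    ``max_failure_rate`` of them fail (the model is then too fragile for
    bootstrap inference).
    """
    if fit is None:
        fit = fit_sem(model, data)
    start = np.array(list(fit.estimates.values()))
    rng = np.random.default_rng(seed)
    n = len(data)
    rows = []
    failed = 0
    for _ in range(n_boot):
        ix = rng.integers(0, n, size=n)
        sample = data.iloc[ix].reset_index(drop=True)
        try:
            r = fit_sem(model, sample, start=start, n_restarts=1)
            if not r.converged:
                failed += 1
                continue
            rows.append(r.estimates)
        except SemError:
            failed += 1
    if n_boot > 0 and failed / n_boot > max_failure_rate:
        raise SemError(f"{failed}/{n_boot} bootstrap replicates failed; "
                       "revise the model before bootstrap inference")
    reps = pd.DataFrame(rows)
    a = (1 - level) / 2
    if len(reps) == 1:
        lo = hi = reps.iloc[0].to_dict()
        warnings.warn("single bootstrap replicate: degenerate CI", UserWarning, stacklevel=2)
    else:
        lo = reps.quantile(a).to_dict()
        hi = reps.quantile(1 - a).to_dict()
    return BootstrapResult(replicates=reps, ci_low={k: float(v) for k, v in lo.items()},
                           ci_high={k: float(v) for k, v in hi.items()},
                           n_requested=n_boot, n_failed=failed, seed=seed, level=level)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def compare_models(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Rank candidate models fitted to the same data by AIC.

    Reports all five criteria (AIC, CMIN/DF, CFI, TLI, RMSEA) and flags
    models where the criteria disagree with the AIC ranking.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ValueError(f"models fitted to different sample sizes {ns}: not comparable")
    rows = []
    for name, f in fits.items():
        rows.append({"model": name, "aic": f.aic, "cmin_df": f.cmin_df,
                     "cfi": f.cfi, "tli": f.tli, "rmsea": f.rmsea})
    tab = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    tab["selected"] = [i == 0 for i in range(len(tab))]
    best_cfi = tab["cfi"].max()
    tab["criteria_agree"] = tab.apply(
        lambda r: bool(r["selected"]) == bool(r["cfi"] == best_cfi), axis=1)
    return tab
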