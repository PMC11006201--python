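"""Synthetic questionnaire data from a known non-recursive latent model.

The generator draws latent outcomes from the simultaneous system

    eta = (I - B)^-1 (Gamma xi + zeta),

where ``eta`` stacks the endogenous constructs (depression, anxiety, somatic
symptoms), ``xi`` the exogenous quantities (latent stress and social support
plus binary/categorical covariates), and ``zeta`` correlated disturbances.
Likert items are produced graded-response style: a continuous indicator
``loading * latent + error`` is cut at fixed thresholds into the item's
declared range.  Because the truth is known exactly, every downstream stage
(scoring, diagnostics, identification, estimation, effect decomposition) can
be tested by parameter recovery.

Default structural coefficients are the published unstandardized direct
effects of the study this battery emulates; loadings default to 0.7 with the
per-construct marker at 1.0 so that a correctly specified analysis model is
on the same scale as the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


ENDOGENOUS = ("depression", "anxiety", "somatic")
EXO_LATENT = ("stress", "social_support")

#: item blocks per construct: (column prefix, count, item_min, item_max)
ITEM_BLOCKS: dict[str, tuple[str, int, int, int]] = {
    "depression": ("phq", 9, 0, 3),
    "anxiety": ("gad", 7, 0, 3),
    "somatic": ("sss", 8, 0, 4),
    "stress": ("pss", 10, 0, 4),
    "social_support": ("osss", 3, 1, 5),
}

#: Bernoulli probabilities for the binary covariates, matching the survey's
#: reported sample composition (coded 1 = risk/exposure category).
DEFAULT_COVARIATES: dict[str, tuple[str, tuple[float, ...]]] = {
    "sex_female": ("bernoulli", (0.6113,)),
    "school_private": ("bernoulli", (0.1022,)),
    "residence_rural": ("bernoulli", (0.3365,)),
    "alcohol_use": ("bernoulli", (0.3575,)),
    "chronic_illness": ("bernoulli", (0.103,)),
    "physical_trauma": ("bernoulli", (0.2197,)),
    "death_loved_one": ("bernoulli", (0.20,)),
    "family_mental_illness": ("bernoulli", (0.0732,)),
    "family_pressure": ("bernoulli", (0.40,)),
    "academic_ability_good": ("bernoulli", (0.4757,)),
    "physically_active": ("bernoulli", (0.1624,)),
    "study_time_high": ("bernoulli", (0.35,)),
    "extra_tutoring": ("bernoulli", (0.30,)),
}

#: published unstandardized direct effects on the three outcomes (loop
#: entries in B, everything else in Gamma); unprinted-but-specified paths
#: (study time, tutoring into somatic) get small defaults.
DEFAULT_B: dict[tuple[str, str], float] = {
    ("depression", "anxiety"): 0.74,
    ("anxiety", "depression"): 0.74,
    ("somatic", "depression"): 0.38,
    ("somatic", "anxiety"): 0.06,
}

#: The unique-instrument coefficients (social support, death of a loved one
#: and family pressure into depression; academic ability and physical trauma
#: into anxiety) are set large enough that the depression<->anxiety loop is
#: strongly identified (first-stage F > 10 at n ~ 1400), reproducing the
#: study's diagnostic regime; the published point estimates for these paths
#: are smaller but are incompatible with that regime, so instrument
#: relevance takes precedence for the default population (the generator
#: exists to make the loop estimable).  Somatic symptoms' instruments (study
#: time, extra tutoring) are kept weak on purpose: the hypothesized somatic
#: feedback paths should fail the instrument screen, as they did in the
#: study, exercising the remediation branch of the pipeline.
DEFAULT_GAMMA: dict[tuple[str, str], float] = {
    ("depression", "stress"): -0.06,
    ("anxiety", "stress"): 0.54,
    ("somatic", "stress"): 0.53,
    ("depression", "alcohol_use"): 0.06,
    ("anxiety", "alcohol_use"): -0.03,
    ("somatic", "alcohol_use"): 0.03,
    ("depression", "chronic_illness"): 0.04,
    ("anxiety", "chronic_illness"): -0.02,
    ("somatic", "chronic_illness"): 0.17,
    ("depression", "social_support"): -0.40,
    ("depression", "death_loved_one"): 0.25,
    ("depression", "family_pressure"): 0.20,
    ("depression", "sex_female"): -0.03,
    ("anxiety", "sex_female"): 0.08,
    ("somatic", "sex_female"): 0.11,
    ("depression", "school_private"): -0.09,
    ("anxiety", "school_private"): 0.12,
    ("somatic", "school_private"): 0.03,
    ("anxiety", "academic_ability_good"): -0.30,
    ("anxiety", "physical_trauma"): 0.35,
    ("somatic", "study_time_high"): 0.05,
    ("somatic", "extra_tutoring"): 0.05,
}


def _default_loadings() -> dict[str, tuple[float, ...]]:
    out = {}
    for construct, (_, k, _, _) in ITEM_BLOCKS.items():
        out[construct] = tuple([1.0] + [0.7] * (k - 1))
    return out


def _default_thresholds() -> dict[str, tuple[float, ...]]:
    """Fixed cutpoints giving right-skewed symptom items (population choice)."""
    per_range = {
        (0, 3): (0.4, 1.1, 1.8),
        (0, 4): (0.3, 0.9, 1.5, 2.1),
        (1, 4): (-0.5, 0.4, 1.2),
        (1, 5): (-0.8, -0.1, 0.7, 1.4),
    }
    out: dict[str, tuple[float, ...]] = {}
    for construct, (prefix, k, lo, hi) in ITEM_BLOCKS.items():
        for i in range(1, k + 1):
            rng = (lo, 4) if (prefix == "osss" and i == 1) else (lo, hi)
            out[f"{prefix}{i}"] = per_range[rng]
    return out


@dataclass
class PopulationSpec:
    """Complete description of the generating population.

    ``b`` and ``gamma`` map (outcome, source) -> unstandardized coefficient;
    ``psi`` is the disturbance covariance of the endogenous constructs and
    ``phi`` the covariance of the exogenous latents (stress, social
    support); covariates are drawn independently from the listed
    distributions.  ``ordinal=False`` skips thresholding and emits the
    continuous indicators directly (used for parameter-recovery studies).
    """

    n: int = 1379
    b: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_B))
    gamma: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    psi: np.ndarray = field(default_factory=lambda: np.array([
        [0.30, 0.05, 0.05],
        [0.05, 0.30, 0.05],
        [0.05, 0.05, 0.30],
    ]))
    phi: np.ndarray = field(default_factory=lambda: np.array([
        [1.00, -0.30],
        [-0.30, 1.00],
    ]))
    loadings: dict[str, tuple[float, ...]] = field(default_factory=_default_loadings)
    thresholds: dict[str, tuple[float, ...]] = field(default_factory=_default_thresholds)
    error_sd: float = 0.6
    covariates: dict[str, tuple[str, tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    missing_rate: float = 0.0003
    ordinal: bool = True

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.allclose(self.psi, self.psi.T) or np.linalg.eigvalsh(self.psi)[0] < -1e-10:
            raise ValueError("psi must be symmetric positive semidefinite")
        if not np.allclose(self.phi, self.phi.T) or np.linalg.eigvalsh(self.phi)[0] < -1e-10:
            raise ValueError("phi must be symmetric positive semidefinite")
        if not (0 <= self.missing_rate < 0.05):
            raise ValueError("missing_rate must be in [0, 0.05)")
        for item, cuts in self.thresholds.items():
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"thresholds for {item!r} must be strictly increasing")
        if np.max(np.abs(np.linalg.eigvals(self.b_matrix()))) >= 1:
            raise ValueError("spectral radius of B must be < 1 (feedback loop explodes)")

    # -- matrix views -------------------------------------------------------
    def b_matrix(self) -> np.ndarray:
        m = len(ENDOGENOUS)
        B = np.zeros((m, m))
        for (out, src), val in self.b.items():
            B[ENDOGENOUS.index(out), ENDOGENOUS.index(src)] = val
        return B

    def exogenous_names(self) -> list[str]:
        return list(EXO_LATENT) + list(self.covariates)

    def gamma_matrix(self) -> np.ndarray:
        exo = self.exogenous_names()
        G = np.zeros((len(ENDOGENOUS), len(exo)))
        for (out, src), val in self.gamma.items():
            if src not in exo:
                raise ValueError(f"gamma source {src!r} is not an exogenous variable")
            G[ENDOGENOUS.index(out), exo.index(src)] = val
        return G

    def to_json(self) -> str:
        d = asdict(self)
        d["b"] = {f"{o}<-{s}": v for (o, s), v in self.b.items()}
        d["gamma"] = {f"{o}<-{s}": v for (o, s), v in self.gamma.items()}
        d["psi"] = self.psi.tolist()
        d["phi"] = self.phi.tolist()
        return json.dumps(d, indent=2)


def simulate_latent(spec: PopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw exogenous quantities and solve the simultaneous system.

    Returns an ``n x (endogenous + exogenous)`` frame of latent scores and
    covariate values; the endogenous columns satisfy
    ``eta = B eta + Gamma xi + zeta`` exactly for the drawn ``xi, zeta``.
    """
    n = spec.n
    B = spec.b_matrix()
    ImB = np.eye(len(ENDOGENOUS)) - B
    if abs(np.linalg.det(ImB)) < 1e-12:
        loop = " <-> ".join(sorted({v for pair in spec.b for v in pair}))
        raise ValueError(f"(I - B) is singular: the feedback loop {loop} is degenerate")
    G = spec.gamma_matrix()

    exo_lat = rng.multivariate_normal(np.zeros(len(EXO_LATENT)), spec.phi, size=n)
    cov_cols = {}
    for name, (kind, params) in spec.covariates.items():
        if kind == "bernoulli":
            cov_cols[name] = rng.binomial(1, params[0], size=n).astype(float)
        elif kind == "categorical":
            w = np.asarray(params, dtype=float)
            cov_cols[name] = rng.choice(len(w), p=w / w.sum(), size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
    xi = np.column_stack([exo_lat] + [cov_cols[c] for c in spec.covariates]) \
        if spec.covariates else exo_lat
    zeta = rng.multivariate_normal(np.zeros(len(ENDOGENOUS)), spec.psi, size=n)
    eta = np.linalg.solve(ImB, (G @ xi.T + zeta.T)).T
    out = pd.DataFrame(eta, columns=list(ENDOGENOUS))
    for j, name in enumerate(spec.exogenous_names()):
        out[name] = xi[:, j]
    return out


def implied_latent_covariance(spec: PopulationSpec) -> np.ndarray:
    """Closed-form covariance of (eta, xi_latent+covariates) implied by the spec.

    Cov(eta) = A (Gamma Phi_full Gamma' + Psi) A' with A = (I-B)^-1, where
    Phi_full is block-diagonal over the latent exogenous covariance and the
    (independent) covariate variances.
    """
    B = spec.b_matrix()
    A = np.linalg.inv(np.eye(len(ENDOGENOUS)) - B)
    G = spec.gamma_matrix()
    var_cov = []
    for kind, params in spec.covariates.values():
        if kind == "bernoulli":
            var_cov.append(params[0] * (1 - params[0]))
        else:
            w = np.asarray(params, dtype=float)
            w = w / w.sum()
            mean = np.sum(np.arange(len(w)) * w)
            var_cov.append(float(np.sum((np.arange(len(w)) - mean) ** 2 * w)))
    k = len(EXO_LATENT) + len(var_cov)
    Phi = np.zeros((k, k))
    Phi[: len(EXO_LATENT), : len(EXO_LATENT)] = spec.phi
    for j, v in enumerate(var_cov):
        Phi[len(EXO_LATENT) + j, len(EXO_LATENT) + j] = v
    top = A @ (G @ Phi @ G.T + spec.psi) @ A.T
    cross = A @ G @ Phi
    full = np.block([[top, cross], [cross.T, Phi]])
    return full


def discretize_items(latent: pd.DataFrame, spec: PopulationSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Cut continuous indicators into Likert categories.

    item = item_min + #{thresholds below loading * latent + error}.  With
    ``spec.ordinal`` False the continuous indicator itself is returned.
    """
    cols = {}
    for construct, (prefix, k, lo, hi) in ITEM_BLOCKS.items():
        lam = spec.loadings[construct]
        if len(lam) != k:
            raise ValueError(f"{construct}: expected {k} loadings, got {len(lam)}")
        scores = latent[construct].to_numpy()
        for i in range(1, k + 1):
            name = f"{prefix}{i}"
            ind = lam[i - 1] * scores + rng.normal(0.0, spec.error_sd, size=len(scores))
            if spec.ordinal:
                cuts = np.asarray(spec.thresholds[name], dtype=float)
                cols[name] = lo + (ind[:, None] > cuts[None, :]).sum(axis=1)
            else:
                cols[name] = ind
    return pd.DataFrame(cols, index=latent.index)


@dataclass
class SyntheticDataset:
    """Item table + covariates, together with the truth that generated it."""

    table: pd.DataFrame
    truth: PopulationSpec
    latent: pd.DataFrame

    def write(self, csv_path: str | Path, truth_path: str | Path | None = None) -> None:
        self.table.to_csv(csv_path, index=False)
        if truth_path is not None:
            Path(truth_path).write_text(self.truth.to_json())


def generate_dataset(spec: PopulationSpec, seed: int) -> SyntheticDataset:
    """Full synthetic survey: items, covariates, MCAR missingness on predictors."""
    rng = np.random.default_rng(seed)
    latent = simulate_latent(spec, rng)
    items = discretize_items(latent, spec, rng)
    table = pd.concat([items, latent[list(spec.covariates)]], axis=1)
    # age is a descriptive covariate only (not in the structural system)
    table["age"] = rng.integers(15, 20, size=spec.n)
    if spec.missing_rate > 0 and spec.covariates:
        pred_cols = list(spec.covariates)
        mask = rng.random((spec.n, len(pred_cols))) < spec.missing_rate
        for j, c in enumerate(pred_cols):
            table.loc[mask[:, j], c] = np.nan
    return SyntheticDataset(table=table, truth=spec, latent=latent)
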