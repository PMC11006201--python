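"""Identification analysis for simultaneous (non-recursive) equation systems.

A structural system with a feedback loop (here depression <-> anxiety, with
somatic symptoms receiving paths from both) is identified only if each loop
equation excludes enough variables.  Three checks are implemented, in
increasing strength:

* unique instruments — every loop variable has at least one exogenous
  variable of its own, excluded from the other loop equations (necessary);
* order condition — per equation, excluded variables >= m - 1 where m is the
  number of endogenous variables (necessary);
* rank condition — the reduced system matrix for each loop equation has rank
  >= m_loop - 1 (sufficient).

Instrument quality is assessed on the data with the Cragg-Donald minimum
eigenvalue F statistic (strength; weak if <= 10) and the Sargan-Hansen
overidentification J test (validity; suspect if p <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SystemSpecError(ValueError):
    """Raised for ill-formed structural system declarations."""


@dataclass(frozen=True)
class StructuralSystem:
    """Named equations of a simultaneous system.

    Parameters
    ----------
    endogenous : tuple of str
        All endogenous variables, in declared order.
    exogenous : tuple of str
        All exogenous variables, in declared order.
    equations : dict
        Outcome -> tuple of regressors (endogenous and/or exogenous names).
        One entry per endogenous variable that has an equation.
    loop : tuple of str
        The endogenous variables participating in a reciprocal loop.
    instruments : dict
        Loop variable -> tuple of instrument names (exogenous variables
        entering that variable's equation but excluded from its loop
        partners' equations).
    """

    endogenous: tuple[str, ...]
    exogenous: tuple[str, ...]
    equations: dict[str, tuple[str, ...]]
    loop: tuple[str, ...] = ()
    instruments: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        declared = set(self.endogenous) | set(self.exogenous)
        for outcome, regs in self.equations.items():
            if outcome not in self.endogenous:
                raise SystemSpecError(f"equation outcome {outcome!r} is not declared endogenous")
            if outcome in regs:
                raise SystemSpecError(f"{outcome!r} regresses on itself")
            for r in regs:
                if r not in declared:
                    raise SystemSpecError(f"undeclared variable {r!r} in equation for {outcome!r}")
        for lv in self.loop:
            if lv not in self.endogenous:
                raise SystemSpecError(f"loop member {lv!r} is not declared endogenous")
        if len(self.loop) == 1:
            raise SystemSpecError("a reciprocal loop needs at least two endogenous variables")

    @property
    def variables(self) -> tuple[str, ...]:
        """Full roster, exogenous first then endogenous (column order)."""
        return self.exogenous + self.endogenous


@dataclass(frozen=True)
class SystemMatrix:
    """0/1 incidence matrix: loop equations (rows) x all variables (columns).

    Entry is 1 iff the column variable appears in that row's equation or is
    the equation's own outcome.
    """

    matrix: np.ndarray
    rows: tuple[str, ...]
    columns: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.rows), columns=list(self.columns))


def build_system_matrix(system: StructuralSystem) -> SystemMatrix:
    """Incidence matrix over the loop equations for the rank condition."""
    rows = tuple(v for v in system.endogenous if v in system.loop) or system.endogenous
    cols = system.variables
    mat = np.zeros((len(rows), len(cols)), dtype=int)
    col_ix = {c: j for j, c in enumerate(cols)}
    for i, outcome in enumerate(rows):
        if outcome not in system.equations:
            raise SystemSpecError(f"no equation declared for loop variable {outcome!r}")
        mat[i, col_ix[outcome]] = 1
        for r in system.equations[outcome]:
            mat[i, col_ix[r]] = 1
    return SystemMatrix(matrix=mat, rows=rows, columns=cols)


@dataclass(frozen=True)
class OrderConditionRow:
    equation: str
    n_included: int
    n_excluded: int
    required: int
    passed: bool


def order_condition(system: StructuralSystem) -> list[OrderConditionRow]:
    """Counting rule: excluded variables per equation >= m - 1.

    Exclusions are counted against the system's declared roster (all
    endogenous plus all exogenous variables); the equation's own outcome
    counts as included.
    """
    total = len(system.variables)
    m = len(system.endogenous)
    out = []
    for outcome, regs in system.equations.items():
        included = len(set(regs)) + 1  # + the outcome itself
        excluded = total - included
        out.append(OrderConditionRow(
            equation=outcome, n_included=included, n_excluded=excluded,
            required=m - 1, passed=excluded >= m - 1,
        ))
    return out


@dataclass(frozen=True)
class RankConditionRow:
    equation: str
    rank: int
    required: int
    passed: bool
    reduced_shape: tuple[int, int]


def rank_condition(sysmat: SystemMatrix, tol: float = 1e-8) -> list[RankConditionRow]:
    """Reduced-matrix rank per loop equation.

    For each row i: delete row i and every column carrying a 1 in row i;
    drop all-zero rows; the rank of what remains (numerical rank, exact for
    0/1 entries) must be >= m_loop - 1.  Deleting duplicate or linearly
    dependent rows by hand is equivalent to taking the matrix rank directly.
    """
    m_loop = sysmat.matrix.shape[0]
    if m_loop == 0 or sysmat.matrix.size == 0:
        raise ValueError("empty system matrix")
    required = m_loop - 1
    out = []
    for i, name in enumerate(sysmat.rows):
        keep_rows = [r for r in range(m_loop) if r != i]
        keep_cols = np.where(sysmat.matrix[i] == 0)[0]
        reduced = sysmat.matrix[np.ix_(keep_rows, keep_cols)]
        nonzero = reduced[~np.all(reduced == 0, axis=1)] if reduced.size else reduced
        rank = int(np.linalg.matrix_rank(nonzero, tol=tol)) if nonzero.size else 0
        out.append(RankConditionRow(
            equation=name, rank=rank, required=required,
            passed=rank >= required, reduced_shape=reduced.shape,
        ))
    return out


@dataclass(frozen=True)
class UniqueInstrumentRow:
    variable: str
    own_instruments: tuple[str, ...]
    unique_instruments: tuple[str, ...]
    passed: bool


def check_unique_instruments(system: StructuralSystem) -> list[UniqueInstrumentRow]:
    """Each loop variable needs >=1 instrument of its own.

    An instrument for loop variable v must (a) not be assigned to any other
    loop variable, (b) be excluded from the other loop equations, and (c)
    appear in v's own equation.  An instrument declared for v but absent
    from v's equation, or present in a partner's equation, is an invalid
    assignment.
    """
    out = []
    for v in system.loop:
        own = tuple(system.instruments.get(v, ()))
        partners = [w for w in system.loop if w != v]
        for z in own:
            if z not in system.equations.get(v, ()):
                raise SystemSpecError(
                    f"instrument {z!r} for {v!r} does not enter {v!r}'s own equation")
            for w in partners:
                if z in system.equations.get(w, ()):
                    raise SystemSpecError(
                        f"instrument {z!r} for {v!r} also enters the equation of {w!r}")
        shared = {z for w in partners for z in system.instruments.get(w, ())}
        unique = tuple(z for z in own if z not in shared)
        out.append(UniqueInstrumentRow(variable=v, own_instruments=own,
                                       unique_instruments=unique, passed=len(unique) >= 1))
    return out


@dataclass(frozen=True)
class IdentificationReport:
    order: list[OrderConditionRow]
    rank: list[RankConditionRow]
    unique_instruments: list[UniqueInstrumentRow]
    identified: bool

    def to_dict(self) -> dict:
        return {
            "order_condition": [vars(r) for r in self.order],
            "rank_condition": [
                {**vars(r), "reduced_shape": list(r.reduced_shape)} for r in self.rank
            ],
            "unique_instruments": [
                {**vars(r), "own_instruments": list(r.own_instruments),
                 "unique_instruments": list(r.unique_instruments)}
                for r in self.unique_instruments
            ],
            "identified": self.identified,
        }


def identification_report(system: StructuralSystem) -> IdentificationReport:
    """Run all three identification checks; the rank condition decides."""
    sysmat = build_system_matrix(system)
    rank = rank_condition(sysmat)
    return IdentificationReport(
        order=order_condition(system),
        rank=rank,
        unique_instruments=check_unique_instruments(system) if system.loop else [],
        identified=all(r.passed for r in rank),
    )


# ---------------------------------------------------------------------------
# Instrument diagnostics on data (2SLS-based)
# ---------------------------------------------------------------------------

def _design(data: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = data[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(f"missing values in columns {cols}; apply listwise deletion first")
    return X


def _residual_maker(X: np.ndarray) -> np.ndarray:
    """Annihilator M = I - X(X'X)^-1 X' (X may have zero columns)."""
    n = X.shape[0]
    if X.shape[1] == 0:
        return np.eye(n)
    Q, _ = np.linalg.qr(X)
    return np.eye(n) - Q @ Q.T


def cragg_donald_f(data: pd.DataFrame, outcome: str, endog_regressors: list[str],
                   exog_regressors: list[str], instruments: list[str]) -> float:
    """Cragg-Donald minimum-eigenvalue first-stage F statistic.

    With a single endogenous regressor this equals the F test of the excluded
    instruments in the first-stage regression.  Values above 10 are the
    conventional strong-instrument threshold.
    """
    if len(instruments) < 1:
        raise ValueError("at least one instrument required")
    n = data.shape[0]
    X = np.column_stack([np.ones(n), _design(data, exog_regressors)]) if exog_regressors \
        else np.ones((n, 1))
    Y2 = _design(data, endog_regressors)
    Z = _design(data, instruments)
    k_x, k_z = X.shape[1], Z.shape[1]
    if n <= k_x + k_z + len(endog_regressors):
        raise ValueError("too few observations for the first-stage regression")
    M_x = _residual_maker(X)
    Y2p = M_x @ Y2
    Zp = M_x @ Z
    ZpZ = Zp.T @ Zp
    if np.linalg.matrix_rank(ZpZ) < k_z:
        raise ValueError("collinear instruments after partialling out exogenous regressors")
    G = Y2p.T @ Zp @ np.linalg.solve(ZpZ, Zp.T @ Y2p)
    Sigma_vv = (Y2p.T @ Y2p - G) / (n - k_x - k_z)
    # symmetrized form Sigma^-1/2 G Sigma^-1/2 via Cholesky keeps eigs real >= 0
    L = np.linalg.cholesky(Sigma_vv)
    Linv = np.linalg.inv(L)
    ev = np.linalg.eigvalsh(Linv @ (G / k_z) @ Linv.T)
    return float(np.min(ev))


@dataclass(frozen=True)
class SarganResult:
    j_stat: float | None
    df: int
    p_value: float | None
    defined: bool
    note: str = ""


def two_stage_least_squares(data: pd.DataFrame, outcome: str, endog_regressors: list[str],
                            exog_regressors: list[str], instruments: list[str]
                            ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Plain 2SLS.  Returns (coefficients, residuals, coefficient names).

    Regressor order: intercept, endogenous regressors, included exogenous.
    """
    n = data.shape[0]
    W = np.column_stack([np.ones(n), _design(data, endog_regressors + exog_regressors)])
    Zfull = np.column_stack([np.ones(n),
                             _design(data, exog_regressors) if exog_regressors else np.empty((n, 0)),
                             _design(data, instruments)])
    y = _design(data, [outcome]).ravel()
    if Zfull.shape[1] < W.shape[1]:
        raise ValueError("underidentified: fewer instruments than endogenous regressors")
    Pz_W = Zfull @ np.linalg.lstsq(Zfull, W, rcond=None)[0]
    beta, *_ = np.linalg.lstsq(Pz_W, y, rcond=None)
    resid = y - W @ beta
    names = ["const"] + endog_regressors + exog_regressors
    return beta, resid, names


def sargan_hansen(data: pd.DataFrame, outcome: str, endog_regressors: list[str],
                  exog_regressors: list[str], instruments: list[str]) -> SarganResult:
    """Sargan J overidentification test (homoskedastic form).

    J = n * R^2 of the 2SLS residual on the full instrument set, chi-square
    with df = #instruments - #endogenous regressors.  Undefined (df = 0) for
    a just-identified equation.
    """
    df = len(instruments) - len(endog_regressors)
    if df <= 0:
        return SarganResult(j_stat=None, df=df, p_value=None, defined=False,
                            note="just-identified equation: test undefined (df=0)")
    _, resid, _ = two_stage_least_squares(data, outcome, endog_regressors,
                                          exog_regressors, instruments)
    n = data.shape[0]
    Zfull = np.column_stack([np.ones(n),
                             _design(data, exog_regressors) if exog_regressors else np.empty((n, 0)),
                             _design(data, instruments)])
    fitted = Zfull @ np.linalg.lstsq(Zfull, resid, rcond=None)[0]  # P_Z u
    j = n * float(fitted @ fitted) / float(resid @ resid)
    p = float(stats.chi2.sf(j, df))
    return SarganResult(j_stat=float(j), df=df, p_value=p, defined=True)


@dataclass(frozen=True)
class InstrumentReport:
    """IV quality for one directed loop edge ``outcome <- source``."""

    outcome: str
    source: str
    cragg_donald: float
    strong: bool
    sargan: SarganResult
    valid: bool | None
    remediation: str

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "source": self.source,
            "cragg_donald_f": self.cragg_donald,
            "strong": self.strong,
            "sargan_j": self.sargan.j_stat,
            "sargan_df": self.sargan.df,
            "sargan_p": self.sargan.p_value,
            "sargan_defined": self.sargan.defined,
            "valid": self.valid,
            "remediation": self.remediation,
        }


def instrument_diagnostics(data: pd.DataFrame, system: StructuralSystem,
                           f_threshold: float = 10.0, alpha: float = 0.05
                           ) -> list[InstrumentReport]:
    """Cragg-Donald strength and Sargan validity for every loop edge.

    Each reciprocal path ``outcome <- source`` is probed pairwise: the
    outcome's equation is estimated by 2SLS with ``source`` as the single
    instrumented regressor (other loop regressors are left out of the
    probe; conditioning on them would inject their endogeneity into the
    test) and the source's unique instruments as excluded instruments.
    A weak or invalid path carries the standard remediation note: delete
    that non-recursive path.
    """
    out = []
    for v in system.loop:
        regs = system.equations[v]
        partners = [r for r in regs if r in system.loop]
        for w in partners:
            exog_in_eq = [r for r in regs if r not in system.endogenous]
            inst = [z for z in system.instruments.get(w, ()) if z not in regs]
            if not inst:
                raise SystemSpecError(
                    f"no usable instruments for the path {v!r} <- {w!r}")
            f = cragg_donald_f(data, v, [w], exog_in_eq, inst)
            sarg = sargan_hansen(data, v, [w], exog_in_eq, inst)
            strong = f > f_threshold
            valid = None if not sarg.defined else (sarg.p_value > alpha)
            remediation = ""
            if not strong or valid is False:
                remediation = (f"weak or invalid instruments: delete the "
                               f"non-recursive path {v} <- {w}")
            out.append(InstrumentReport(outcome=v, source=w, cragg_donald=f,
                                        strong=strong, sargan=sarg, valid=valid,
                                        remediation=remediation))
    return out


# ---------------------------------------------------------------------------
# The study's published three-equation system (depression y1, anxiety y2,
# somatic symptoms y3 over exogenous covariates x2-x18)
# ---------------------------------------------------------------------------

STUDY_EXOGENOUS = tuple(f"x{i}" for i in range(2, 19))

#: x2 alcohol use, x3 chronic illness, x4 physical activity, x5 family mental
#: illness, x7 school type, x11 death of a loved one, x12 social support,
#: x13 physical trauma, x14 study time, x15 extra tutoring, x16 family
#: academic pressure, x17 self-rated academic ability, x18 stress.
STUDY_SYSTEM = StructuralSystem(
    endogenous=("y1", "y2", "y3"),
    exogenous=STUDY_EXOGENOUS,
    equations={
        "y1": ("x2", "x3", "x4", "x5", "x7", "x11", "x12", "x16", "x18", "y2", "y3"),
        "y2": ("x2", "x3", "x4", "x5", "x7", "x13", "x17", "x18", "y1", "y3"),
        "y3": ("x2", "x3", "x4", "x5", "x7", "x14", "x15", "x18", "y1", "y2"),
    },
    loop=("y1", "y2", "y3"),
    instruments={
        "y1": ("x11", "x12", "x16"),
        "y2": ("x13", "x17"),
        "y3": ("x14", "x15"),
    },
)
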