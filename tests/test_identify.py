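"""Identification: system matrix, order/rank conditions, IV diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.sandbox.regression.gmm import IV2SLS

from nrsem.identify import (STUDY_SYSTEM, StructuralSystem, SystemSpecError,
                            build_system_matrix, check_unique_instruments,
                            cragg_donald_f, order_condition, rank_condition,
                            sargan_hansen, two_stage_least_squares)

# the three-equation depression/anxiety/somatic system's published 0/1 rows
PRINTED_ROWS = {
    "y1": "11110100011000101111",
    "y2": "11110100000100011111",
    "y3": "11110100000011001111",
}


class TestSystemMatrix:
    def test_reproduces_published_rows_bit_exactly(self):
        sm_ = build_system_matrix(STUDY_SYSTEM)
        assert sm_.columns == STUDY_SYSTEM.exogenous + STUDY_SYSTEM.endogenous
        for name, row in zip(sm_.rows, sm_.matrix):
            assert "".join(map(str, row)) == PRINTED_ROWS[name]

    def test_single_equation_marks_regressor_and_outcome(self):
        sys1 = StructuralSystem(endogenous=("y1",), exogenous=("x2",),
                                equations={"y1": ("x2",)})
        m = build_system_matrix(sys1)
        assert m.as_frame().loc["y1", "x2"] == 1
        assert m.as_frame().loc["y1", "y1"] == 1

    def test_undeclared_variable_is_named_in_the_error(self):
        with pytest.raises(SystemSpecError, match="ghost"):
            StructuralSystem(endogenous=("y1", "y2"), exogenous=("x1",),
                             equations={"y1": ("ghost", "y2"), "y2": ("x1", "y1")},
                             loop=("y1", "y2"))


class TestOrderCondition:
    def test_equation_with_every_variable_fails_for_m_ge_2(self):
        sys_ = StructuralSystem(
            endogenous=("y1", "y2"), exogenous=("x1", "x2"),
            equations={"y1": ("x1", "x2", "y2"), "y2": ("x1", "y1")},
            loop=("y1", "y2"))
        rows = {r.equation: r for r in order_condition(sys_)}
        assert rows["y1"].n_excluded == 0 and not rows["y1"].passed
        assert rows["y2"].n_excluded == 1 and rows["y2"].passed

    def test_matches_brute_force_counting_on_enumerated_small_systems(self):
        # enumerate all 2-endogenous systems over 2 exogenous regrs sets
        exo = ("x1", "x2")
        pool = ["x1", "x2", "y2"]
        for r1 in itertools.chain.from_iterable(
                itertools.combinations(pool, k) for k in range(len(pool) + 1)):
            regs2 = ("x1", "y1")
            try:
                sys_ = StructuralSystem(endogenous=("y1", "y2"), exogenous=exo,
                                        equations={"y1": tuple(r1), "y2": regs2},
                                        loop=("y1", "y2"))
            except SystemSpecError:
                continue
            rows = {r.equation: r for r in order_condition(sys_)}
            total = 4  # roster size
            for eq, regs in (("y1", r1), ("y2", regs2)):
                excluded = total - (len(set(regs)) + 1)
                assert rows[eq].n_excluded == excluded
                assert rows[eq].passed == (excluded >= 1)

    def test_order_failure_implies_rank_failure(self, rng):
        # necessity: whenever the counting rule fails, the rank rule must too
        for _ in range(200):
            m, k = 3, 5
            mat = np.zeros((m, m + k), dtype=int)
            for i in range(m):
                mat[i, rng.random(m + k) < 0.6] = 1
                mat[i, k + i] = 1
            names_e = tuple(f"y{i}" for i in range(m))
            names_x = tuple(f"x{j}" for j in range(k))
            eqs = {}
            for i in range(m):
                regs = [names_x[j] for j in range(k) if mat[i, j]]
                regs += [names_e[j] for j in range(m) if j != i and mat[i, k + j]]
                eqs[names_e[i]] = tuple(regs)
            sys_ = StructuralSystem(endogenous=names_e, exogenous=names_x,
                                    equations=eqs, loop=names_e)
            order = {r.equation: r.passed for r in order_condition(sys_)}
            rank = {r.equation: r.passed
                    for r in rank_condition(build_system_matrix(sys_))}
            for eq in names_e:
                if not order[eq]:
                    assert not rank[eq]


class TestRankCondition:
    def test_published_system_has_rank_two_everywhere(self):
        rows = rank_condition(build_system_matrix(STUDY_SYSTEM))
        assert all(r.rank == 2 and r.passed for r in rows)

    def test_all_ones_matrix_fails_with_empty_reduction(self):
        sys_ = StructuralSystem(
            endogenous=("y1", "y2"), exogenous=("x1",),
            equations={"y1": ("x1", "y2"), "y2": ("x1", "y1")},
            loop=("y1", "y2"))
        rows = rank_condition(build_system_matrix(sys_))
        assert all(r.rank == 0 and not r.passed for r in rows)

    def test_agrees_with_svd_rank_oracle_on_random_sparse_systems(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 5))
            k = int(rng.integers(m, 8))
            mat = (rng.random((m, m + k)) < 0.4).astype(int)
            mat[:, k:] |= np.eye(m, dtype=int)
            from nrsem.identify import SystemMatrix
            sm_ = SystemMatrix(matrix=mat,
                               rows=tuple(f"y{i}" for i in range(m)),
                               columns=tuple(f"v{j}" for j in range(m + k)))
            for i, row in enumerate(rank_condition(sm_)):
                keep_rows = [r for r in range(m) if r != i]
                keep_cols = np.where(mat[i] == 0)[0]
                reduced = mat[np.ix_(keep_rows, keep_cols)].astype(float)
                sv = np.linalg.svd(reduced, compute_uv=False) if reduced.size else []
                svd_rank = int(np.sum(np.asarray(sv) > 1e-8))
                assert row.rank == svd_rank


class TestUniqueInstruments:
    def test_published_instrument_pattern_passes(self):
        assert all(r.passed for r in check_unique_instruments(STUDY_SYSTEM))

    def test_shared_single_instrument_fails_both_variables(self):
        sys_ = StructuralSystem(
            endogenous=("y1", "y2"), exogenous=("x1", "x2", "x3"),
            equations={"y1": ("x1", "x2", "y2"), "y2": ("x1", "x3", "y1")},
            loop=("y1", "y2"),
            instruments={"y1": ("x2",), "y2": ("x3",)})
        assert all(r.passed for r in check_unique_instruments(sys_))
        shared = StructuralSystem(
            endogenous=("y1", "y2"), exogenous=("x1", "x2"),
            equations={"y1": ("x1", "x2", "y2"), "y2": ("x1", "y1")},
            loop=("y1", "y2"),
            instruments={"y1": ("x2",), "y2": ("x2",)})
        with pytest.raises(SystemSpecError):
            check_unique_instruments(shared)

    def test_instrument_entering_partner_equation_is_invalid(self):
        bad = StructuralSystem(
            endogenous=("y1", "y2"), exogenous=("x1", "x2"),
            equations={"y1": ("x1", "x2", "y2"), "y2": ("x2", "y1")},
            loop=("y1", "y2"),
            instruments={"y1": ("x2",), "y2": ()})
        with pytest.raises(SystemSpecError, match="x2"):
            check_unique_instruments(bad)


def _iv_data(rng, n=500, pi=0.6, invalid=0.0):
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    u = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
    x = pi * z1 + pi * z2 + u[:, 0]
    y = 0.8 * x + invalid * z1 + u[:, 1]
    return pd.DataFrame({"y": y, "x": x, "z1": z1, "z2": z2})


class TestCraggDonald:
    def test_matches_statsmodels_2sls_coefficients(self, rng):
        d = _iv_data(rng, n=800)
        beta, _, _ = two_stage_least_squares(d, "y", ["x"], [], ["z1", "z2"])
        fitted = IV2SLS(d["y"].to_numpy(),
                        np.column_stack([np.ones(800), d["x"]]),
                        np.column_stack([np.ones(800), d[["z1", "z2"]]])).fit()
        assert np.allclose(beta, fitted.params, atol=1e-10)

    def test_equals_squared_first_stage_t_for_single_instrument(self, rng):
        d = _iv_data(rng, n=600)
        f = cragg_donald_f(d, "y", ["x"], [], ["z1"])
        first = sm.OLS(d["x"], sm.add_constant(d["z1"])).fit()
        assert f == pytest.approx(float(first.tvalues.iloc[1] ** 2), rel=1e-10)

    def test_irrelevant_instruments_rarely_exceed_threshold(self, rng):
        hits = 0
        for _ in range(200):
            d = _iv_data(rng, n=500, pi=0.0)
            if cragg_donald_f(d, "y", ["x"], [], ["z1", "z2"]) > 10:
                hits += 1
        assert hits / 200 <= 0.05

    def test_near_deterministic_first_stage_gives_enormous_f(self, rng):
        n = 300
        z = rng.normal(size=n)
        x = z + rng.normal(0, 1e-3, size=n)
        d = pd.DataFrame({"y": x + rng.normal(size=n), "x": x, "z": z})
        assert cragg_donald_f(d, "y", ["x"], [], ["z"]) > 1e4

    def test_collinear_instruments_error(self, rng):
        d = _iv_data(rng, n=200)
        d["z_dup"] = d["z1"]
        with pytest.raises(ValueError, match="collinear"):
            cragg_donald_f(d, "y", ["x"], [], ["z1", "z_dup"])


class TestSargan:
    def test_just_identified_equation_is_undefined_not_a_number(self, rng):
        res = sargan_hansen(_iv_data(rng), "y", ["x"], [], ["z1"])
        assert not res.defined and res.j_stat is None and res.df == 0

    def test_size_under_valid_instruments(self, rng):
        rejections = 0
        for _ in range(500):
            d = _iv_data(rng, n=500)
            res = sargan_hansen(d, "y", ["x"], [], ["z1", "z2"])
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / 500 <= 0.09

    def test_power_against_instrument_in_outcome_equation(self, rng):
        rejections = 0
        for _ in range(100):
            d = _iv_data(rng, n=500, invalid=0.4)
            res = sargan_hansen(d, "y", ["x"], [], ["z1", "z2"])
            rejections += res.p_value < 0.05
        assert rejections / 100 > 0.5


def test_removing_a_loop_path_never_decreases_exclusions():
    pruned_eqs = {k: tuple(v for v in regs if v != "y3")
                  for k, regs in STUDY_SYSTEM.equations.items()}
    pruned = StructuralSystem(
        endogenous=STUDY_SYSTEM.endogenous, exogenous=STUDY_SYSTEM.exogenous,
        equations=pruned_eqs, loop=STUDY_SYSTEM.loop,
        instruments=STUDY_SYSTEM.instruments)
    before = {r.equation: r.n_excluded for r in order_condition(STUDY_SYSTEM)}
    after = {r.equation: r.n_excluded for r in order_condition(pruned)}
    assert all(after[eq] >= before[eq] for eq in before)
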