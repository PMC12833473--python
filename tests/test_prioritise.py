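"""Bross-formula scoring, zero-cell correction, ranking, IV-like flags."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdpslib import (AssociationTable, CohortMaster, bross_bias,
                     build_association_tables, flag_iv_like, prioritise,
                     select_top, zero_cell_correct)
from hdpslib.errors import AlignmentError


def _table(e1, e0, n1, n0, d1, d0, m1, m0, cid="c"):
    return AssociationTable(cid, e1, e0, n1, n0, d1, d0, m1, m0)


class TestBuildAssociationTables:
    def test_hand_cross_tab(self):
        master = CohortMaster(pd.DataFrame({
            "patient_id": ["a", "b", "c", "d"],
            "exposure": [1, 0, 1, 0],
            "outcome": [1, 1, 0, 0],
            "time_to_event": [1.0] * 4,
        }))
        X = pd.DataFrame({"c": [1, 1, 0, 0]},
                         index=pd.Index(["a", "b", "c", "d"],
                                        name="patient_id"))
        (t,) = build_association_tables(X, master)
        assert (t.e1, t.e0, t.n1, t.n0) == (1, 1, 2, 2)
        assert (t.d1, t.d0, t.m1, t.m0) == (2, 0, 2, 2)

    def test_all_zero_covariate_is_degenerate_not_fatal(self, toy_master):
        X = pd.DataFrame({"c": [0] * 6},
                         index=pd.Index(toy_master.patient_ids,
                                        name="patient_id"))
        (t,) = build_association_tables(X, toy_master)
        assert t.e1 == t.e0 == 0
        corrected = zero_cell_correct(t)
        assert corrected.corrected

    def test_misaligned_patient_sets_raise(self, toy_master):
        X = pd.DataFrame({"c": [1, 0]},
                         index=pd.Index(["p0", "zzz"], name="patient_id"))
        with pytest.raises(AlignmentError, match="zzz"):
            build_association_tables(X, toy_master)

    def test_cells_match_nested_loop_oracle(self):
        rng = np.random.default_rng(3)
        n = 200
        pids = [f"p{i}" for i in range(n)]
        expo = rng.integers(0, 2, n)
        outc = rng.integers(0, 2, n)
        if expo.sum() in (0, n):  # guard: fixture needs both arms
            expo[0] = 1 - expo[0]
        master = CohortMaster(pd.DataFrame({
            "patient_id": pids, "exposure": expo, "outcome": outc,
            "time_to_event": np.ones(n)}))
        C = rng.integers(0, 2, n)
        X = pd.DataFrame({"c": C}, index=pd.Index(pids, name="patient_id"))
        (t,) = build_association_tables(X, master)
        e1 = sum(1 for i in range(n) if C[i] == 1 and expo[i] == 1)
        e0 = sum(1 for i in range(n) if C[i] == 1 and expo[i] == 0)
        d1 = sum(1 for i in range(n) if C[i] == 1 and outc[i] == 1)
        d0 = sum(1 for i in range(n) if C[i] == 0 and outc[i] == 1)
        assert (t.e1, t.e0, t.d1, t.d0) == (e1, e0, d1, d0)
        assert (t.n1, t.n0) == (expo.sum(), n - expo.sum())
        assert (t.m1, t.m0) == (C.sum(), n - C.sum())


class TestZeroCellCorrect:
    def test_adds_tenth_to_all_four_cells_of_zero_table(self):
        t = _table(e1=5, e0=3, n1=10, n0=10, d1=0, d0=5, m1=10, m0=90)
        c = zero_cell_correct(t)
        # outcome table had the zero: (0,10,5,85) -> (0.1,10.1,5.1,85.1)
        assert c.outcome_cells == pytest.approx((0.1, 10.1, 5.1, 85.1),
                                                abs=1e-12)
        # exposure table untouched
        assert c.exposure_cells == t.exposure_cells
        assert c.corrected_outcome and not c.corrected_exposure

    def test_identity_when_no_zero(self):
        t = _table(3, 2, 10, 10, 2, 8, 5, 15)
        assert zero_cell_correct(t) == t

    def test_idempotent(self):
        t = _table(0, 2, 10, 10, 1, 1, 2, 18)
        once = zero_cell_correct(t)
        assert zero_cell_correct(once) == once

    def test_randomised_zero_tables_yield_finite_positive_rrs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            cells = rng.integers(0, 4, 8).astype(float)
            t = _table(e1=cells[0], e0=cells[1],
                       n1=cells[0] + cells[2] + 1, n0=cells[1] + cells[3] + 1,
                       d1=cells[4], d0=cells[5],
                       m1=cells[4] + cells[6] + 1, m0=cells[5] + cells[7] + 1)
            c = zero_cell_correct(t)
            for rr in (c.rr_ce, c.rr_cd):
                assert np.isfinite(rr) and rr > 0


class TestBrossBias:
    def test_equal_prevalence_gives_no_bias(self):
        bias, alb = bross_bias(0.2, 0.2, 3.0)
        assert bias == pytest.approx(1.0) and alb == pytest.approx(0.0)

    def test_null_outcome_association_gives_no_bias(self):
        bias, _ = bross_bias(0.7, 0.1, 1.0)
        assert bias == pytest.approx(1.0)

    def test_published_expression_direct_arithmetic(self):
        bias, alb = bross_bias(0.5, 0.1, 2.0)
        assert bias == pytest.approx(1.5 / 1.1, rel=1e-14)
        assert alb == pytest.approx(math.log(15 / 11), rel=1e-14)

    def test_nonpositive_rr_is_domain_error(self):
        with pytest.raises(ValueError):
            bross_bias(0.5, 0.1, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99),
           st.floats(1.0, 20.0))
    def test_antisymmetry_in_prevalences(self, pc1, pc0, rr):
        b1, a1 = bross_bias(pc1, pc0, rr)
        b2, a2 = bross_bias(pc0, pc1, rr)
        assert b1 * b2 == pytest.approx(1.0, rel=1e-12)
        assert a1 == pytest.approx(a2, rel=1e-9, abs=1e-12)

    def test_strictly_increasing_in_pc1_for_harmful_rr(self):
        vals = [bross_bias(p, 0.2, 2.5)[0] for p in np.linspace(0.0, 1.0, 11)]
        assert all(b2 > b1 for b1, b2 in zip(vals, vals[1:]))

    def test_protective_rr_inverted_for_ranking(self):
        # rr and 1/rr must score identically when inversion is on
        b_harm, a_harm = bross_bias(0.4, 0.1, 2.0)
        b_prot, a_prot = bross_bias(0.4, 0.1, 0.5)
        assert a_prot == pytest.approx(a_harm, rel=1e-12)
        b_raw, _ = bross_bias(0.4, 0.1, 0.5, invert_protective=False)
        assert b_raw != pytest.approx(b_prot)


class TestPrioritise:
    def _tables(self, k, seed=0):
        rng = np.random.default_rng(seed)
        tables = []
        for i in range(k):
            n1, n0 = 50, 60
            e1, e0 = rng.integers(0, 51), rng.integers(0, 61)
            m1 = max(int(e1 + e0), 1)
            m0 = 110 - m1 if 110 - m1 > 0 else 1
            d1, d0 = rng.integers(0, m1 + 1), rng.integers(0, m0 + 1)
            tables.append(_table(e1, e0, n1, n0, d1, d0, m1, m0,
                                 cid=f"c{i:02d}"))
        return tables

    def test_sorted_by_abs_log_bias_with_unique_ranks(self):
        report = prioritise(self._tables(50))
        assert list(report["rank"]) == list(range(1, 51))
        assert (report["abs_log_bias"].diff().dropna() <= 0).all()

    def test_ties_broken_lexicographically(self):
        t1 = _table(10, 5, 20, 20, 3, 2, 15, 25, cid="b")
        t2 = _table(10, 5, 20, 20, 3, 2, 15, 25, cid="a")
        report = prioritise([t1, t2])
        assert list(report["covariate_id"]) == ["a", "b"]

    def test_ordering_matches_recompute_and_sort_oracle(self):
        tables = self._tables(50, seed=42)
        report = prioritise(tables)
        scored = []
        for t in tables:
            c = zero_cell_correct(t)
            _, alb = bross_bias(c.pc1, c.pc0, c.rr_cd)
            scored.append((-alb, t.covariate_id))
        expected = [cid for _, cid in sorted(scored)]
        assert list(report["covariate_id"]) == expected

    def test_ranking_invariant_to_input_order(self):
        tables = self._tables(30, seed=9)
        a = prioritise(tables)
        b = prioritise(list(reversed(tables)))
        pd.testing.assert_frame_equal(a, b)

    def test_correction_keeps_every_covariate_finite(self):
        tables = self._tables(100, seed=1)
        report = prioritise(tables, correction=True)
        assert len(report) == 100
        assert np.isfinite(report["abs_log_bias"]).all()


class TestSelectTop:
    def test_paper_style_grid_and_clamp(self):
        report = prioritise(TestPrioritise()._tables(5))
        assert select_top(report, 0) == []
        assert len(select_top(report, 10)) == 5
        assert select_top(report, 3) == report["covariate_id"].head(3).tolist()

    def test_remove_iv_like_drops_flagged_before_topn(self):
        report = prioritise(TestPrioritise()._tables(30, seed=2))
        report = report.copy()
        flagged = report["covariate_id"].iloc[0]
        report.loc[report["covariate_id"] == flagged, "iv_like"] = True
        out = select_top(report, 5, remove_iv_like=True)
        assert flagged not in out and len(out) == 5


class TestFlagIvLike:
    def test_both_criteria_met(self):
        assert flag_iv_like(math.exp(1.6), math.exp(0.4)) is True

    def test_strict_boundaries_false(self):
        assert flag_iv_like(math.exp(1.5), math.exp(0.1)) is False
        assert flag_iv_like(math.exp(2.0), math.exp(0.5)) is False

    def test_grid_matches_direct_inequality_oracle(self):
        for lce in np.linspace(-3, 3, 13):
            for lcd in np.linspace(-1.5, 1.5, 13):
                got = flag_iv_like(math.exp(lce), math.exp(lcd))
                assert got == (abs(lce) > 1.5 and abs(lcd) < 0.5)
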