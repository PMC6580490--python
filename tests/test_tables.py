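"""2x2 table construction, index derivation, and exact reconstruction."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from liftrr import (
    InconsistentIndicesError,
    IndexSet,
    InvalidTableError,
    UndefinedIndexError,
    from_counts,
    indices_from_table,
    table_from_indices,
)

from conftest import WORKED_COUNTS


class TestFromCounts:
    def test_worked_example_total(self, worked_table):
        assert worked_table.n == 333_250
        assert worked_table.n_exposed == 71_849
        assert worked_table.n_outcome == 29_679

    def test_single_subject_table_is_valid_but_degenerate(self):
        t = from_counts(1, 0, 0, 0)
        assert t.n == 1
        assert t.has_zero_margin

    @pytest.mark.parametrize(
        "cells",
        [(0, 0, 0, 0), (-1, 1, 1, 1), (1.5, 1, 1, 1)],
        ids=["all-zero", "negative", "non-integer"],
    )
    def test_invalid_cells_rejected(self, cells):
        with pytest.raises(InvalidTableError):
            from_counts(*cells)

    def test_integral_floats_accepted(self):
        assert from_counts(1.0, 2, 3, 4).a == 1


class TestIndicesFromTable:
    def test_worked_example_indices(self, worked_table):
        idx = indices_from_table(worked_table)
        assert round(idx.support, 3) == 0.023
        assert round(idx.confidence, 2) == 0.11
        assert round(idx.lift, 2) == 1.22
        assert idx.n_total == 333_250

    def test_independence_table(self):
        idx = indices_from_table(from_counts(1, 1, 1, 1))
        assert (idx.support, idx.confidence, idx.lift) == (0.25, 0.5, 1.0)

    def test_perfect_association(self):
        idx = indices_from_table(from_counts(5, 0, 0, 5))
        assert (idx.support, idx.confidence, idx.lift) == (0.5, 1.0, 2.0)

    @pytest.mark.parametrize(
        "cells",
        [(0, 0, 1, 1), (0, 1, 0, 1), (0, 1, 1, 1)],
        ids=["no-exposed", "no-outcome", "zero-support"],
    )
    def test_undefined_indices_raise(self, cells):
        with pytest.raises(UndefinedIndexError):
            indices_from_table(from_counts(*cells))

    def test_exact_mode_returns_fractions(self, worked_table):
        idx = indices_from_table(worked_table, exact=True)
        assert idx.lift == Fraction(7828 * 333_250, 71_849 * 29_679)

    def test_two_lift_definitions_agree(self, worked_table):
        # P(O|E)/P(O) and P(OE)/(P(O)P(E)) are the same number
        idx = indices_from_table(worked_table)
        p_e, p_o = idx.p_exposure, idx.p_outcome
        joint_form = idx.support / (p_e * p_o)
        assert joint_form == pytest.approx(idx.lift, rel=1e-12)


class TestIndexSetValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(support=0.0, confidence=0.5, lift=1.0),
            dict(support=0.6, confidence=0.5, lift=1.0),
            dict(support=0.5, confidence=1.2, lift=1.5),
            dict(support=0.2, confidence=0.5, lift=0.4),
            dict(support=0.2, confidence=0.5, lift=1.0, n_total=0),
        ],
        ids=[
            "zero-support",
            "support-over-confidence",
            "confidence-over-one",
            "lift-below-confidence",
            "zero-n",
        ],
    )
    def test_invalid_triples_rejected(self, kwargs):
        with pytest.raises(InconsistentIndicesError):
            IndexSet(**kwargs)

    def test_rounded_printed_triple_validates(self):
        # two-decimal printed values must pass despite rounding
        idx = IndexSet(support=0.023, confidence=0.11, lift=1.22)
        assert 0 < idx.p_exposure < 1
        assert 0 < idx.p_outcome < 1


class TestTableFromIndices:
    def test_worked_example_reconstructs(self, worked_table):
        idx = indices_from_table(worked_table)
        assert table_from_indices(idx).as_tuple() == WORKED_COUNTS

    def test_brute_force_n4(self):
        # (support, confidence, lift, N=4): the only table among all
        # 2x2 tables with N=4 matching (0.25, 0.5, 1) is (1,1,1,1)
        matches = []
        for a in range(5):
            for b in range(5 - a):
                for c in range(5 - a - b):
                    d = 4 - a - b - c
                    if a == 0 or a + b == 0 or a + c == 0:
                        continue
                    if (a / 4, a / (a + b), a * 4 / ((a + b) * (a + c))) == (
                        0.25,
                        0.5,
                        1.0,
                    ):
                        matches.append((a, b, c, d))
        assert matches == [(1, 1, 1, 1)]
        idx = IndexSet(support=0.25, confidence=0.5, lift=1.0, n_total=4)
        assert table_from_indices(idx).as_tuple() == (1, 1, 1, 1)

    def test_requires_n_total(self):
        with pytest.raises(InconsistentIndicesError):
            table_from_indices(IndexSet(support=0.25, confidence=0.5, lift=1.0))

    def test_coarsely_rounded_inputs_fail_loudly(self):
        # the worked example printed at 2 significant digits cannot be
        # mapped back to cell counts
        idx = IndexSet(support=0.023, confidence=0.11, lift=1.22, n_total=333_250)
        with pytest.raises(InconsistentIndicesError):
            table_from_indices(idx)

    @given(
        a=st.integers(1, 20),
        b=st.integers(0, 20),
        c=st.integers(0, 20),
        d=st.integers(0, 20),
    )
    def test_round_trip_property(self, a, b, c, d):
        """indices -> table is the exact inverse of table -> indices."""
        if a + c == 0 or c + d == 0 or b + d == 0:
            return
        t = from_counts(a, b, c, d)
        assert table_from_indices(indices_from_table(t)).as_tuple() == t.as_tuple()
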