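"""The lift -> RR / OR conversion equations and their algebraic properties."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from liftrr import (
    ConversionInputError,
    IndexSet,
    effects_from_indices,
    from_counts,
    indices_from_table,
    lift,
    lift_upper_bound,
    odds_ratio,
    prevalences,
    relative_risk,
    rr_from_lift,
    or_from_lift,
    rr_lift_curve,
)

from conftest import positive_margin_tables

INF = float("inf")


class TestRRFromLift:
    def test_worked_example(self):
        assert round(rr_from_lift(1.2233507239249042, 71849 / 333250), 2) == 1.30

    @pytest.mark.parametrize("p", [0.01, 0.22, 0.5, 0.9])
    def test_null_preserved(self, p):
        assert rr_from_lift(1.0, p) == pytest.approx(1.0, rel=1e-15)

    def test_matches_direct_rr_on_small_tables(self):
        for t in positive_margin_tables(6):
            if t.a == 0:
                continue
            lf = lift(t, exact=True)
            p_e, _ = prevalences(t, exact=True)
            assert rr_from_lift(lf, p_e) == relative_risk(t, exact=True), t

    def test_structural_zero_cell_maps_to_infinity(self):
        t = from_counts(3, 7, 0, 10)
        lf = lift(t, exact=True)
        p_e, _ = prevalences(t, exact=True)
        assert rr_from_lift(lf, p_e) == INF

    def test_inconsistent_product_rejected(self):
        with pytest.raises(ConversionInputError):
            rr_from_lift(3.0, 0.5)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_prevalence_rejected(self, p):
        with pytest.raises(ConversionInputError):
            rr_from_lift(1.2, p)

    def test_eq3_identity_rr_minus_one(self):
        # RR - 1 = (lift - 1) / (1 - P(E) lift), the rearranged form
        for t in positive_margin_tables(5, min_cell=1):
            lf = lift(t, exact=True)
            p_e, _ = prevalences(t, exact=True)
            rr = rr_from_lift(lf, p_e)
            assert rr - 1 == (lf - 1) / (1 - p_e * lf), t


class TestORFromLift:
    def test_worked_example(self):
        assert (
            round(
                or_from_lift(1.2233507239249042, 71849 / 333250, 29679 / 333250), 2
            )
            == 1.34
        )

    def test_null_preserved(self):
        assert or_from_lift(1.0, 0.3, 0.1) == pytest.approx(1.0, rel=1e-15)

    def test_matches_direct_or_on_small_tables(self):
        for t in positive_margin_tables(6):
            if t.a == 0:
                continue
            lf = lift(t, exact=True)
            p_e, p_o = prevalences(t, exact=True)
            assert or_from_lift(lf, p_e, p_o) == odds_ratio(t, exact=True), t


class TestEffectsFromIndices:
    def test_exact_worked_example(self, worked_table):
        eff = effects_from_indices(indices_from_table(worked_table))
        assert round(eff.rr, 2) == 1.30
        assert round(eff.or_, 2) == 1.34
        assert round(eff.p_exposure, 2) == 0.22
        assert round(eff.p_outcome, 3) == 0.089

    def test_rounded_printed_inputs_drift(self):
        # converting the two-decimal printed indices lands near but not at
        # the exact value: documented rounding drift, not a defect
        eff = effects_from_indices(
            IndexSet(support=0.023, confidence=0.11, lift=1.22)
        )
        assert eff.p_exposure == pytest.approx(0.209, abs=5e-4)
        assert eff.rr == pytest.approx(1.2953, abs=5e-4)
        assert eff.rr != pytest.approx(1.30336, abs=5e-4)  # the exact value

    def test_universal_exposure_rejected(self):
        with pytest.raises(ConversionInputError):
            effects_from_indices(IndexSet(support=0.3, confidence=0.3, lift=1.0))


class TestLiftUpperBound:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.01, 100), (0.05, 20), (0.1, 10), (0.3, 3.3), (0.5, 2), (0.7, 1.4)],
    )
    def test_published_caption_values(self, p, expected):
        assert round(lift_upper_bound(p), 1) == expected

    def test_joint_bound_takes_minimum(self):
        assert lift_upper_bound(0.2, 0.1) == 5.0
        assert lift_upper_bound(0.1, 0.2) == 5.0

    @pytest.mark.parametrize("p", [0.0, 1.0, -1.0])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ConversionInputError):
            lift_upper_bound(p)


class TestRRLiftCurve:
    def test_single_point_curves(self):
        assert rr_lift_curve(0.3, [1.0]) == [(1.0, 1.0)]
        [(x, rr)] = rr_lift_curve(0.22, [1.22])
        assert round(rr, 2) == 1.30

    def test_rare_exposure_hugs_diagonal(self):
        grid = [1 + 0.05 * k for k in range(21)]  # 1.0 .. 2.0
        for x, rr in rr_lift_curve(0.01, grid):
            assert rr == pytest.approx(x, rel=0.02)

    def test_ratio_monotone_in_lift(self):
        grid = [1 + 0.1 * k for k in range(20)]
        pairs = rr_lift_curve(0.3, grid)
        ratios = [rr / x for x, rr in pairs]
        assert all(r2 >= r1 for r1, r2 in zip(ratios, ratios[1:]))

    def test_grid_beyond_bound_rejected_with_listing(self):
        with pytest.raises(ConversionInputError) as err:
            rr_lift_curve(0.5, [1.5, 2.0, 2.5])
        assert "2.0" in str(err.value) and "2.5" in str(err.value)


class TestMonotonicityProperties:
    def test_denominator_between_zero_and_one(self):
        # 1 - P(E) lift = c/(a+c) on any table: in (0, 1] always
        for t in positive_margin_tables(6):
            lf = lift(t, exact=True)
            p_e, _ = prevalences(t, exact=True)
            den = 1 - p_e * lf
            assert 0 <= den <= 1, t
            assert (den == 0) == (t.c == 0), t

    @given(
        p_e=st.floats(0.01, 0.9),
        lift_lo=st.floats(1.0, 3.0),
        step=st.floats(0.001, 0.5),
    )
    def test_ratio_monotone_in_lift_property(self, p_e, lift_lo, step):
        lift_hi = lift_lo + step
        if p_e * lift_hi >= 0.999:
            return
        r1 = rr_from_lift(lift_lo, p_e) / lift_lo
        r2 = rr_from_lift(lift_hi, p_e) / lift_hi
        assert r2 >= r1 * (1 - 1e-12)

    @given(
        lf=st.floats(1.0, 5.0),
        p_lo=st.floats(0.01, 0.9),
        step=st.floats(0.001, 0.5),
    )
    def test_ratio_monotone_in_prevalence_property(self, lf, p_lo, step):
        p_hi = p_lo + step
        if p_hi >= 1 or p_hi * lf >= 0.999:
            return
        r1 = rr_from_lift(lf, p_lo) / lf
        r2 = rr_from_lift(lf, p_hi) / lf
        assert r2 >= r1 * (1 - 1e-12)

    def test_closed_form_ratio(self):
        # RR / lift = (1 - P(E)) / (1 - P(E) lift), in exact arithmetic
        for t in positive_margin_tables(5, min_cell=1):
            lf = lift(t, exact=True)
            p_e, _ = prevalences(t, exact=True)
            rr = rr_from_lift(lf, p_e)
            assert rr / lf == (1 - p_e) / (1 - p_e * lf), t
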