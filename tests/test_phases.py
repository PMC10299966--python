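"""Five-phase classification: boundaries, min rule, knot ratios, bound spans."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import msnt
from msnt.core import DomainError

from conftest import make_estimate


def brute_force_phase(value, knots):
    """Largest phase such that the value lies strictly below all higher knots."""
    phase = 1
    for p in range(2, 6):
        if all(value < knots[j] for j in range(p - 1)):
            phase = p
    return phase


class TestClassifyIndicator:
    @pytest.mark.parametrize("value, expected", [
        (700, 1),      # boundary belongs to the higher-mortality phase (>= 700)
        (700.01, 1),
        (699.99, 2),
        (19.99, 5),    # phase 5 is < 20
        (20, 4),
    ])
    def test_mmr_boundaries(self, value, expected, thresholds):
        assert msnt.classify_indicator(value, thresholds.mmr_knots) == expected

    def test_sbn_knot_value_has_not_passed(self, thresholds):
        assert msnt.classify_indicator(55, thresholds.sbn_knots) == 2

    def test_negative_value_rejected(self, thresholds):
        with pytest.raises(DomainError):
            msnt.classify_indicator(-1, thresholds.mmr_knots)

    @given(value=st.floats(min_value=0, max_value=1500, allow_nan=False))
    def test_agrees_with_brute_force_scan(self, value, thresholds):
        assert msnt.classify_indicator(value, thresholds.mmr_knots) == \
            brute_force_phase(value, thresholds.mmr_knots)

    @given(lo=st.floats(0, 1500), hi=st.floats(0, 1500))
    def test_monotone_decreasing_mortality_never_lowers_phase(self, lo, hi, thresholds):
        lo, hi = min(lo, hi), max(lo, hi)
        assert msnt.classify_indicator(lo, thresholds.mmr_knots) >= \
            msnt.classify_indicator(hi, thresholds.mmr_knots)


class TestClassifyCountry:
    def test_min_rule_holds_back_the_combined_phase(self):
        # mmr 650 -> phase 2, sbn 85 -> phase 1, combined phase 1
        a = msnt.classify_country(make_estimate(mmr=650, sbr=40, nmr=45))
        assert (a.phase_mmr, a.phase_sbn, a.phase) == (2, 1, 1)

    def test_below_all_knots_is_phase_5(self):
        a = msnt.classify_country(make_estimate(mmr=10, sbr=5, nmr=5))
        assert a.phase == 5

    def test_both_at_knot_stay_in_phase_2(self):
        a = msnt.classify_country(make_estimate(mmr=300, sbr=25, nmr=30))
        assert (a.phase_mmr, a.phase_sbn, a.phase) == (2, 2, 2)

    def test_combine_mode_can_move_a_boundary_case(self):
        # sbr + nmr = 55 (phase 2) but the exact combination is below the knot
        est = make_estimate(mmr=250, sbr=25, nmr=30)
        assert msnt.classify_country(est, mode="approximate").phase_sbn == 2
        assert msnt.classify_country(est, mode="exact").phase_sbn == 3

    def test_grid_oracle_exact_agreement(self, thresholds):
        """classify_country equals the brute-force scan on a dense grid that
        covers all 25 indicator-phase combinations and every knot boundary."""
        mmr_grid = np.unique(np.concatenate([
            np.linspace(0, 1200, 196), np.array(thresholds.mmr_knots)]))
        sbn_grid = np.unique(np.concatenate([
            np.linspace(0, 120, 196), np.array(thresholds.sbn_knots)]))
        seen = set()
        for mmr in mmr_grid:
            for sbn in sbn_grid:
                est = make_estimate(mmr=float(mmr), sbr=0.0, nmr=float(sbn))
                got = msnt.classify_country(est, thresholds, mode="approximate")
                exp_m = brute_force_phase(mmr, thresholds.mmr_knots)
                exp_s = brute_force_phase(sbn, thresholds.sbn_knots)
                assert (got.phase_mmr, got.phase_sbn) == (exp_m, exp_s)
                assert got.phase == min(exp_m, exp_s)
                seen.add((exp_m, exp_s))
        assert len(seen) == 25

    def test_variant_bound_ordering(self, small_panel):
        """Lower bounds mean lower mortality, hence an equal-or-later phase."""
        for est in small_panel:
            lo = msnt.classify_country(est, variant="lower").phase
            pt = msnt.classify_country(est, variant="point").phase
            hi = msnt.classify_country(est, variant="upper").phase
            assert lo >= pt >= hi


class TestThresholds:
    @pytest.mark.parametrize("knots", [
        (700, 300, 100), (700, 300, 300, 20), (700, 300, 100, -5),
        (20, 100, 300, 700),
    ])
    def test_invalid_knot_vectors_rejected(self, knots):
        with pytest.raises(DomainError):
            msnt.PhaseThresholds(mmr_knots=knots)

    def test_nmr_only_alternative_is_valid(self):
        t = msnt.PhaseThresholds(mmr_knots=msnt.DEFAULT_MMR_KNOTS,
                                 sbn_knots=msnt.NMR_ONLY_KNOTS)
        assert t.sbn_knots == (45, 30, 15, 5)


class TestKnotRatios:
    def test_default_ratios(self, thresholds):
        kr = msnt.knot_ratios(thresholds)
        assert kr.rounded == (11, 18, 30, 75)
        assert kr.unrounded == pytest.approx((80 / 7, 55 / 3, 30.0, 75.0))
        assert list(kr.unrounded) == sorted(kr.unrounded)  # strictly increasing
        assert all(a < b for a, b in zip(kr.unrounded, kr.unrounded[1:]))

    def test_homogeneity_all_ratios_equal(self):
        t = msnt.PhaseThresholds(mmr_knots=(800, 400, 200, 40),
                                 sbn_knots=(80, 40, 20, 4))
        assert msnt.knot_ratios(t).unrounded == pytest.approx((10, 10, 10, 10))

    def test_custom_thresholds(self):
        t = msnt.PhaseThresholds(mmr_knots=(800, 400, 200, 40),
                                 sbn_knots=(80, 55, 30, 15))
        assert msnt.knot_ratios(t).unrounded == pytest.approx((10, 13.75, 15, 37.5))


class TestUncertaintyPhaseSpan:
    def test_degenerate_bounds_give_zero_mean(self):
        panel = [make_estimate(mmr=m, sbr=s, nmr=n, country=f"C{i}")
                 for i, (m, s, n) in enumerate([(650, 40, 45), (90, 10, 12),
                                                (15, 4, 5)])]
        res = msnt.uncertainty_phase_span(panel, year=2000)
        assert res.mean == 0.0

    def test_two_country_hand_case(self):
        # one country's bounds straddle the 100-knot (phases 3 vs 2 -> span 1),
        # the other's do not (span 0): mean 0.5
        a = make_estimate(mmr=95, sbr=15, nmr=18, country="A", halfwidth=0.2)
        b = make_estimate(mmr=150, sbr=15, nmr=18, country="B", halfwidth=0.2)
        res = msnt.uncertainty_phase_span([a, b], year=2000)
        spans = dict(zip(res.per_country["country_id"], res.per_country["span"]))
        assert spans == {"A": 1, "B": 0}
        assert res.mean == 0.5

    def test_missing_bounds_excluded_and_counted(self):
        a = make_estimate(mmr=95, sbr=15, nmr=18, country="A", halfwidth=0.2)
        b = msnt.CountryYearEstimate("B", 2000, mmr=100, sbr=10, nmr=10)
        res = msnt.uncertainty_phase_span([a, b], year=2000)
        assert res.n_excluded == 1
        assert len(res.per_country) == 1

    def test_empty_year_raises(self):
        a = make_estimate(mmr=95, sbr=15, nmr=18, halfwidth=0.2)
        with pytest.raises(DomainError):
            msnt.uncertainty_phase_span([a], year=1999)

    def test_wide_bounds_give_positive_mean(self, small_panel):
        res = msnt.uncertainty_phase_span(small_panel)
        assert res.mean > 0
        assert (res.per_country["span"] >= 0).all()
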