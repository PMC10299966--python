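"""Phase profiles, benchmarking, cause-group shares and abortion scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import msnt
from msnt.core import DomainError


def panel_from(values_by_phase, indicator="tfr"):
    rows = [(f"C{p}{i}", p, indicator, v)
            for p, values in values_by_phase.items()
            for i, v in enumerate(values)]
    return pd.DataFrame(rows, columns=["country_id", "phase", "indicator", "value"])


class TestPhaseSummaries:
    def test_linear_interpolation_quartiles(self):
        profs = msnt.phase_summaries(panel_from({2: [1, 2, 3, 4, 5]}), "tfr")
        p = profs[2]
        assert (p.median, p.q1, p.q3, p.n) == (3, 2, 4, 5)

    def test_single_country_collapses_quartiles(self):
        p = msnt.phase_summaries(panel_from({4: [2.2]}), "tfr")[4]
        assert p.median == p.q1 == p.q3 == 2.2

    def test_empty_phases_absent_not_zero(self):
        profs = msnt.phase_summaries(panel_from({1: [6.0, 6.2]}), "tfr")
        assert set(profs) == {1}

    def test_unknown_indicator_lists_available(self):
        with pytest.raises(DomainError, match="tfr"):
            msnt.phase_summaries(panel_from({1: [6.0]}), "nope")

    def test_missing_values_dropped_and_counted(self):
        df = panel_from({1: [6.0, np.nan, 6.4]})
        p = msnt.phase_summaries(df, "tfr")[1]
        assert p.n == 2

    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=12),
           st.floats(0.1, 10), st.randoms(use_true_random=False))
    def test_permutation_invariant_and_scale_equivariant(self, values, c, rnd):
        base = msnt.phase_summaries(panel_from({3: values}), "tfr")[3]
        shuffled = list(values)
        rnd.shuffle(shuffled)
        perm = msnt.phase_summaries(panel_from({3: shuffled}), "tfr")[3]
        assert (perm.median, perm.q1, perm.q3) == (base.median, base.q1, base.q3)
        scaled = msnt.phase_summaries(
            panel_from({3: [c * v for v in values]}), "tfr")[3]
        assert scaled.median == pytest.approx(c * base.median, rel=1e-9)
        assert scaled.q1 == pytest.approx(c * base.q1, rel=1e-9)
        assert scaled.q3 == pytest.approx(c * base.q3, rel=1e-9)

    def test_generator_medians_recovered(self, synthetic_panel, recovery_config,
                                         synthetic_assignments):
        joined = synthetic_panel.covariates.merge(
            synthetic_assignments[["country_id", "year", "phase"]],
            on=["country_id", "year"])
        spec = recovery_config.covariates["tfr"]
        profs = msnt.phase_summaries(joined, "tfr")
        for phase, prof in profs.items():
            assert prof.median == pytest.approx(spec.medians[phase - 1], rel=0.10)


class TestBenchmark:
    # phase-3 total-fertility reference profile (median 2.8, IQR 2.0-3.5)
    PROFILE = msnt.PhaseProfile(3, "tfr", 30, 2.8, 2.0, 3.5)

    def test_median_is_typical(self):
        assert msnt.benchmark_country(self.PROFILE.median, self.PROFILE) == "typical"

    def test_just_above_iqr(self):
        assert msnt.benchmark_country(3.5 + 1e-9, self.PROFILE) == "above_iqr"
        assert msnt.benchmark_country(3.5, self.PROFILE) == "typical"

    def test_tfr_4_is_above_phase3_iqr(self):
        assert msnt.benchmark_country(4.0, self.PROFILE) == "above_iqr"

    def test_tolerance_widens_band(self):
        assert msnt.benchmark_country(4.0, self.PROFILE, tolerance=0.2) == "typical"

    def test_below_iqr(self):
        assert msnt.benchmark_country(1.2, self.PROFILE) == "below_iqr"

    def test_benchmark_table(self):
        out = msnt.benchmark_table({"tfr": 4.0}, {"tfr": {3: self.PROFILE}}, 3)
        assert list(out["flag"]) == ["above_iqr"]


class TestCauseGroupShares:
    NEONATAL = msnt.load_default_cause_mapping("neonatal")

    def test_single_cause_all_in_one_group(self):
        shares = msnt.cod_group_shares({"prematurity": 12}, self.NEONATAL)
        assert shares.as_tuple() == (0, 100, 0, 0)

    def test_early_phase_neonatal_fixture(self):
        # high-mortality-phase shares: infections 24, prematurity 41,
        # intrapartum 26, other 9
        shares = msnt.cod_group_shares(
            {"sepsis": 24, "prematurity": 41, "intrapartum": 26, "other": 9},
            self.NEONATAL)
        assert shares.as_tuple() == pytest.approx((24, 41, 26, 9))

    def test_order_invariance(self):
        table = {"sepsis": 24, "prematurity": 41, "intrapartum": 26, "other": 9}
        rev = dict(reversed(list(table.items())))
        assert msnt.cod_group_shares(table, self.NEONATAL) == \
            msnt.cod_group_shares(rev, self.NEONATAL)

    def test_strict_mode_names_unmapped_cause(self):
        with pytest.raises(DomainError, match="mystery"):
            msnt.cod_group_shares({"mystery": 5}, self.NEONATAL)

    def test_lenient_mode_routes_to_other(self):
        shares = msnt.cod_group_shares({"mystery": 5, "sepsis": 5},
                                       self.NEONATAL, strict=False)
        assert shares.other == pytest.approx(50)

    def test_negative_deaths_rejected(self):
        with pytest.raises(DomainError):
            msnt.cod_group_shares({"sepsis": -1}, self.NEONATAL)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=8).filter(
        lambda v: sum(v) > 0))
    def test_shares_sum_to_100(self, deaths):
        causes = ["sepsis", "pneumonia", "prematurity", "congenital_anomalies",
                  "intrapartum", "birth_asphyxia", "tetanus", "other"]
        table = dict(zip(causes, deaths))
        shares = msnt.cod_group_shares(table, self.NEONATAL)
        assert sum(shares.as_tuple()) == pytest.approx(100, abs=1e-6)

    def test_all_three_default_mappings_load(self):
        for which in ("maternal", "stillbirth", "neonatal"):
            mapping = msnt.load_default_cause_mapping(which)
            assert mapping, which
        maternal = msnt.load_default_cause_mapping("maternal")
        assert maternal["abortion_complications"] == "group1"
        assert maternal["haemorrhage"] == "group3"


class TestAbortionScore:
    GROUNDS = msnt.profiles.DEFAULT_ABORTION_GROUNDS

    def policy(self, n_permitted):
        return msnt.AbortionPolicy(
            {g: i < n_permitted for i, g in enumerate(self.GROUNDS)})

    @pytest.mark.parametrize("n, expected", [(0, 0), (3, 60), (5, 100)])
    def test_equal_weight_counting(self, n, expected):
        assert msnt.abortion_score(self.policy(n)) == expected

    def test_monotone_in_permitted_grounds(self):
        scores = [msnt.abortion_score(self.policy(n)) for n in range(6)]
        assert scores == sorted(scores)

    def test_custom_weights(self):
        p = msnt.AbortionPolicy({g: g == "on_request" for g in self.GROUNDS})
        assert msnt.abortion_score(p, weights=[1, 1, 1, 1, 6]) == 60

    def test_wrong_ground_count_rejected(self):
        with pytest.raises(DomainError):
            msnt.AbortionPolicy({"a": True}, grounds=("a",))
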