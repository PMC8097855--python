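"""Quantification math: ΔΔCt, copies, MAF, CMI, standard curves, LOD."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methyloutlier import (
    Calibration,
    CtTable,
    ValidationError,
    copies_from_ct,
    delta_ct_series,
    genome_equivalents,
    lod_summary,
    maf,
    percent_methylation_ddct,
    quantify_sample,
    simulate_dilution_series,
    simulate_spikein_experiment,
    standard_curve_stats,
)


class TestPercentMethylation:
    def test_matching_delta_ct_is_100_percent(self, calibration):
        # ΔCt_sample = ΔCt_control = 1.0 for cg054
        assert percent_methylation_ddct(26.0, 25.0, calibration, "cg054") == pytest.approx(100.0)

    def test_ddct_arithmetic(self, calibration):
        # ΔCt_control 1.0, ΔCt_sample 4.32 -> 100·2^(−3.32) ≈ 10.0
        pm = percent_methylation_ddct(29.32, 25.0, calibration, "cg054")
        assert pm == pytest.approx(100 * 2 ** -3.32)
        assert pm == pytest.approx(10.0, abs=0.05)

    def test_no_amp_marker_is_zero(self, calibration):
        assert percent_methylation_ddct(None, 25.0, calibration, "cg054") == 0.0

    def test_no_amp_actb_is_an_error(self, calibration):
        with pytest.raises(ValidationError, match="loading control"):
            percent_methylation_ddct(30.0, None, calibration, "cg054")

    def test_uncalibrated_marker_is_an_error(self, calibration):
        with pytest.raises(ValidationError, match="calibrated"):
            percent_methylation_ddct(30.0, 25.0, calibration, "cgXXX")

    def test_values_above_100_not_clipped(self, calibration):
        pm = percent_methylation_ddct(24.0, 25.0, calibration, "cg054")
        assert pm == pytest.approx(400.0)

    def test_round_trip_recovers_true_percent(self, calibration):
        # noiseless model: marker Ct implied by a given percent methylation
        for true_pm in (0.5, 3.0, 42.0, 100.0):
            delta_sample = calibration.control_delta_ct["cg054"] - math.log2(true_pm / 100)
            pm = percent_methylation_ddct(25.0 + delta_sample, 25.0, calibration, "cg054")
            assert pm == pytest.approx(true_pm, rel=1e-9)


class TestCopies:
    def test_reference_ct_gives_reference_copies(self, calibration):
        assert copies_from_ct(25.0, calibration) == pytest.approx(606.0)

    def test_one_cycle_halves(self, calibration):
        assert copies_from_ct(26.0, calibration) == pytest.approx(303.0)

    def test_no_amp_is_zero(self, calibration):
        assert copies_from_ct(None, calibration) == 0.0

    def test_marker_reference_offset(self, calibration):
        # cg054 reference Ct = 25 + 1 at 606 copies
        assert copies_from_ct(26.0, calibration, "cg054") == pytest.approx(606.0)

    def test_round_trip_exact(self, calibration):
        for copies in (1.0, 5.0, 606.0, 1e5):
            ct = 25.0 - math.log2(copies / 606.0)
            assert copies_from_ct(ct, calibration) == pytest.approx(copies, rel=1e-12)

    def test_monotone_in_ct(self, calibration):
        assert copies_from_ct(24.0, calibration) > copies_from_ct(25.0, calibration)


class TestGenomeEquivalents:
    def test_2ng_is_606_copies(self):
        assert round(genome_equivalents(2000.0, 3.3)) == 606

    def test_63pg_is_10_cells(self):
        assert round(genome_equivalents(63.0, 6.6)) == 10

    def test_zero_mass(self):
        assert genome_equivalents(0.0) == 0.0

    def test_nonpositive_genome_mass_rejected(self):
        with pytest.raises(ValidationError):
            genome_equivalents(10.0, 0.0)


class TestMaf:
    @pytest.mark.parametrize(
        "marker, actb, expected",
        [(1408, 2826, 49.82), (1127, 2826, 39.88), (84, 2496, 3.37), (0, 100, 0.0)],
    )
    def test_plasma_worked_examples(self, marker, actb, expected):
        assert round(maf(marker, actb), 2) == expected

    def test_no_loading_control_signal(self):
        with pytest.raises(ValidationError, match="loading control"):
            maf(10, 0)

    @given(
        marker=st.floats(0, 1e6),
        actb=st.floats(1e-3, 1e6),
        factor=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, marker, actb, factor):
        assert maf(marker * factor, actb * factor) == pytest.approx(
            maf(marker, actb), rel=1e-9
        )


class TestQuantifySample:
    def _table(self, rows):
        return CtTable.from_records(rows)

    def test_all_markers_no_amp(self, calibration):
        ct = self._table(
            [("P", "ACTB", 1, 25.0), ("P", "cg054", 1, None), ("P", "SCG3", 1, None)]
        )
        res = quantify_sample(ct, calibration, ["cg054", "SCG3"])
        assert res.cmi == 0.0 and res.total_maf == 0.0
        assert all(q.dropout for q in res.markers.values())

    def test_total_maf_sums_unrounded_components(self, calibration):
        # copies chosen to reproduce 1408 and 1127 against 2826 ACTB copies
        actb_ct = 25.0 - math.log2(2826 / 606)
        ct_cg054 = 26.0 - math.log2(1408 / 606)
        ct_scg3 = 27.0 - math.log2(1127 / 606)
        ct = self._table(
            [("P", "ACTB", 1, actb_ct), ("P", "cg054", 1, ct_cg054),
             ("P", "SCG3", 1, ct_scg3)]
        )
        res = quantify_sample(ct, calibration, ["cg054", "SCG3"])
        assert res.actb_copies == pytest.approx(2826)
        assert res.markers["cg054"].copies == pytest.approx(1408)
        assert res.total_maf == pytest.approx(1408 / 2826 * 100 + 1127 / 2826 * 100)
        assert round(res.total_maf, 2) == 89.70

    def test_single_marker_panel_additivity(self, calibration):
        ct = self._table(
            [("P", "ACTB", 1, 25.0), ("P", "cg054", 1, 27.0), ("P", "SCG3", 1, 28.0)]
        )
        both = quantify_sample(ct, calibration, ["cg054", "SCG3"])
        single_a = quantify_sample(ct, calibration, ["cg054"])
        single_b = quantify_sample(ct, calibration, ["SCG3"])
        assert both.cmi == pytest.approx(single_a.cmi + single_b.cmi)

    def test_replicates_averaged_and_partial_dropout_flagged(self, calibration):
        ct = self._table(
            [("P", "ACTB", 1, 25.0), ("P", "ACTB", 2, 25.4),
             ("P", "cg054", 1, 27.0), ("P", "cg054", 2, None)]
        )
        res = quantify_sample(ct, calibration, ["cg054"])
        assert res.actb_ct == pytest.approx(25.2)
        assert res.markers["cg054"].partial_dropout
        assert not res.markers["cg054"].dropout

    def test_missing_actb_is_an_error(self, calibration):
        ct = self._table([("P", "cg054", 1, 27.0)])
        with pytest.raises(ValidationError, match="ACTB"):
            quantify_sample(ct, calibration, ["cg054"])

    def test_late_ct_coerced_to_no_amp_with_warning(self, calibration):
        ct = self._table([("P", "ACTB", 1, 25.0), ("P", "cg054", 1, 41.0)])
        with pytest.warns(UserWarning, match="cycle"):
            res = quantify_sample(ct, calibration, ["cg054"])
        assert res.markers["cg054"].dropout

    def test_lower_marker_ct_never_decreases_quantities(self, calibration):
        base = quantify_sample(
            self._table([("P", "ACTB", 1, 25.0), ("P", "cg054", 1, 30.0)]),
            calibration, ["cg054"])
        more = quantify_sample(
            self._table([("P", "ACTB", 1, 25.0), ("P", "cg054", 1, 28.0)]),
            calibration, ["cg054"])
        q0, q1 = base.markers["cg054"], more.markers["cg054"]
        assert q1.copies > q0.copies
        assert q1.percent_methylation > q0.percent_methylation
        assert q1.maf > q0.maf


class TestStandardCurve:
    def test_exact_doubling_model_is_perfectly_linear(self):
        series = [(level, [5.0 - math.log2(level / 100)] * 3)
                  for level in (100, 50, 25, 12.5, 6.25, 3)]
        curve = standard_curve_stats(series)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.slope == pytest.approx(-1.0)
        assert all(cv == 0.0 for cv in curve.cv_per_level.values())

    def test_noisy_series_stays_linear(self):
        ct = simulate_dilution_series(ct_noise_sd=0.2, seed=8)
        curve = standard_curve_stats(delta_ct_series(ct, "cg054"))
        assert curve.r_squared > 0.90

    def test_needs_three_levels(self):
        with pytest.raises(ValidationError, match="3 distinct"):
            standard_curve_stats([(100, [1.0]), (50, [2.0])])


class TestLodSummary:
    def _cal(self):
        return Calibration(control_delta_ct={"cg054": 0.0, "SCG3": 0.0})

    def test_complete_separation_gives_2_of_924(self):
        ct = simulate_spikein_experiment(levels=(5, 0), seed=21)
        summary = lod_summary(ct, self._cal(), ["cg054", "SCG3"])
        assert summary.p_values[5.0] == pytest.approx(2 / 924)
        zero = summary.total_maf[summary.total_maf["level"] == 0.0]
        assert (zero["total_maf"] == 0.0).all()

    def test_one_rank_crossing_gives_4_of_924(self):
        # direct construction: one spiked replicate below the top blank
        rows = []
        for rep, v in enumerate([26.0, 26.5, 27.0, 27.5, 28.0, 33.0], start=1):
            rows += [(f"s_5", "cg054", rep, v), (f"s_5", "ACTB", rep, 25.0)]
        for rep, v in enumerate([32.0] + [None] * 5, start=1):
            rows += [(f"s_0", "cg054", rep, v), (f"s_0", "ACTB", rep, 25.0)]
        ct = CtTable.from_records(rows)
        summary = lod_summary(ct, Calibration(control_delta_ct={"cg054": 0.0}), ["cg054"])
        assert summary.p_values[5.0] == pytest.approx(4 / 924)

    def test_identical_distributions_give_p_1(self):
        rows = []
        for level in (5, 0):
            for rep in range(1, 7):
                rows += [(f"s_{level}", "ACTB", rep, 25.0),
                         (f"s_{level}", "cg054", rep, 30.0)]
        ct = CtTable.from_records(rows)
        summary = lod_summary(ct, Calibration(control_delta_ct={"cg054": 0.0}), ["cg054"])
        assert summary.p_values[5.0] == 1.0

    def test_dropout_counts_per_level(self):
        ct = simulate_spikein_experiment(levels=(40, 5, 0), seed=2)
        summary = lod_summary(ct, self._cal(), ["cg054", "SCG3"])
        assert (summary.dropout_counts.loc[0.0] == 6).all()
        assert summary.dropout_counts.values.min() >= 0

    def test_missing_zero_level_rejected(self):
        with pytest.raises(ValidationError, match="0-copy"):
            simulate_spikein_experiment(levels=(40, 5))
        ct = simulate_spikein_experiment(levels=(5, 0), seed=1)
        trimmed = CtTable(ct.records[ct.records["sample_id"] != "spike_0"].copy())
        with pytest.raises(ValidationError, match="0-copy"):
            lod_summary(trimmed, self._cal(), ["cg054", "SCG3"])
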