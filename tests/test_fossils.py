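"""Time-bin construction and fossil diversification statistics."""

import numpy as np
import pandas as pd
import pytest

from errorshift import BinningConfig, TimeBin, build_bins, diversification_rate, eutherian_proportion
from errorshift.fossils import bins_to_frame, toy_stage_table


def stage_row(stage, start, end, en=5, er=20, mn=10, mr=100):
    return {
        "stage": stage, "start_Ma": start, "end_Ma": end,
        "eutherian_new": en, "eutherian_richness": er,
        "mammal_new": mn, "mammal_richness": mr,
    }


def make_bin(name, start, end, en, er, mn, mr, **kw):
    return TimeBin(name, start, end, en, er, mn, mr, **kw)


class TestTimeBin:
    def test_invariants(self):
        with pytest.raises(ValueError, match="start age"):
            make_bin("x", 10, 10, 1, 2, 3, 4)
        with pytest.raises(ValueError, match="non-negative"):
            make_bin("x", 10, 5, -1, 2, 3, 4)
        with pytest.raises(ValueError, match="exceed standing"):
            make_bin("x", 10, 5, 5, 2, 3, 4)

    def test_duration(self):
        assert make_bin("x", 83.6, 72.1, 1, 2, 3, 4).duration_ma == pytest.approx(11.5)


class TestBuildBins:
    def test_all_stages_above_threshold_stay_unchanged(self):
        df = pd.DataFrame([stage_row("A", 100, 90), stage_row("B", 90, 80), stage_row("C", 80, 70)])
        bins = build_bins(df, BinningConfig(min_mammal_species=80, fixed_bins=()))
        assert [b.name for b in bins] == ["A", "B", "C"]

    def test_adjacent_small_stages_merge(self):
        df = pd.DataFrame([stage_row("A", 100, 90, mr=50), stage_row("B", 90, 80, mr=40)])
        bins = build_bins(df, BinningConfig(min_mammal_species=80, fixed_bins=()))
        assert len(bins) == 1
        assert bins[0].name == "A-B"
        assert bins[0].mammal_richness == 90
        assert bins[0].stages == ("A", "B")
        assert (bins[0].start_ma, bins[0].end_ma) == (100, 80)

    def test_fixed_bins_kept_as_is(self):
        df = pd.DataFrame(
            [stage_row("A", 100, 90, mr=50), stage_row("Campanian", 90, 80, mr=200),
             stage_row("B", 80, 70, mr=90)]
        )
        with pytest.warns(UserWarning, match="flagged"):
            bins = build_bins(df, BinningConfig(min_mammal_species=80))
        assert [b.name for b in bins] == ["A", "Campanian", "B"]
        assert bins[0].flagged and not bins[1].flagged

    def test_partition_no_gaps(self):
        bins = build_bins(toy_stage_table(), BinningConfig())
        for older, younger in zip(bins, bins[1:]):
            assert older.end_ma == pytest.approx(younger.start_ma)

    def test_non_contiguous_stages_rejected(self):
        df = pd.DataFrame([stage_row("A", 100, 90), stage_row("B", 85, 80)])
        with pytest.raises(ValueError, match="contiguous"):
            build_bins(df, BinningConfig())

    def test_toy_table_bin_structure(self):
        bins = build_bins(toy_stage_table(), BinningConfig())
        assert [b.name for b in bins] == [
            "Turonian-Coniacian", "Santonian", "Campanian", "Maastrichtian", "Paleocene", "Ypresian",
        ]
        assert bins[0].mammal_richness == 95  # 50 + 45 merged


class TestDiversificationRate:
    def bins(self):
        return [
            make_bin("P", 110, 100, 5, 40, 10, 100),
            make_bin("Q", 100, 90, 20, 50, 30, 120),
        ]

    def test_hand_arithmetic(self):
        rates = diversification_rate(self.bins(), allow_missing_previous=True)
        # 20 new / (10 Ma x 40 previous standing) = 0.05
        assert rates.loc["Q", "rate"] == pytest.approx(0.05)

    def test_zero_new_appearances_gives_zero(self):
        b = [make_bin("P", 110, 100, 5, 40, 10, 100), make_bin("Q", 100, 90, 0, 50, 30, 120)]
        rates = diversification_rate(b, allow_missing_previous=True)
        assert rates.loc["Q", "rate"] == 0.0

    def test_doubling_duration_halves_rate(self):
        b2 = [self.bins()[0], make_bin("Q", 100, 80, 20, 50, 30, 120)]
        r1 = diversification_rate(self.bins(), allow_missing_previous=True).loc["Q", "rate"]
        r2 = diversification_rate(b2, allow_missing_previous=True).loc["Q", "rate"]
        assert r2 == pytest.approx(r1 / 2)

    def test_missing_previous_without_override_raises(self):
        with pytest.raises(ValueError, match="no previous bin"):
            diversification_rate(self.bins())

    def test_previous_override(self):
        b = self.bins() + [make_bin("R", 90, 80, 10, 60, 20, 130)]
        rates = diversification_rate(b, {"R": "P", "P": "Q"})
        assert rates.loc["R", "previous_bin"] == "P"
        assert rates.loc["R", "rate"] == pytest.approx(10 / (10 * 40))

    def test_zero_previous_richness_flagged_nan(self):
        b = [make_bin("P", 110, 100, 0, 0, 10, 100), make_bin("Q", 100, 90, 20, 50, 30, 120)]
        rates = diversification_rate(b, allow_missing_previous=True)
        assert np.isnan(rates.loc["Q", "rate"]) and rates.loc["Q", "flagged"]


class TestEutherianProportion:
    def test_all_eutherian_gives_one(self):
        b = [make_bin("P", 110, 100, 40, 50, 40, 60)]
        assert eutherian_proportion(b).loc["P", "proportion"] == 1.0

    def test_group_average_is_unweighted_mean(self):
        b = [make_bin("P", 110, 100, 10, 50, 40, 60), make_bin("Q", 100, 90, 30, 60, 60, 80)]
        out = eutherian_proportion(b, {"both": ("P", "Q")})
        assert out.loc["both", "mean_proportion"] == pytest.approx(0.375)  # mean(0.25, 0.5)
        assert out.loc["both", "pooled_proportion"] == pytest.approx(40 / 100)

    def test_zero_denominator_flagged(self):
        b = [make_bin("P", 110, 100, 0, 10, 0, 50)]
        out = eutherian_proportion(b)
        assert np.isnan(out.loc["P", "proportion"]) and out.loc["P", "flagged"]
        with pytest.raises(ValueError, match="no new mammal"):
            eutherian_proportion(b, {"g": ("P",)})

    def test_counts_are_unitless_and_scale_free(self):
        b = [make_bin("P", 110, 100, 10, 50, 40, 60), make_bin("Q", 100, 90, 30, 60, 60, 80)]
        scaled = [
            make_bin("P", 110, 100, 20, 100, 80, 120),
            make_bin("Q", 100, 90, 60, 120, 120, 160),
        ]
        a = eutherian_proportion(b)["proportion"]
        c = eutherian_proportion(scaled)["proportion"]
        assert np.allclose(a, c)


class TestToyTableStatistics:
    def test_headline_proportions_by_hand(self):
        """On the synthetic toy table: Campanian 10/40, Maastrichtian 12/40
        -> mean 0.275; Paleocene 42/50 = 0.84."""
        bins = build_bins(toy_stage_table(), BinningConfig())
        out = eutherian_proportion(
            bins,
            {"CampMaas": ("Campanian", "Maastrichtian"), "Paleocene": ("Paleocene",)},
        )
        assert out.loc["CampMaas", "mean_proportion"] == pytest.approx((0.25 + 0.30) / 2)
        assert out.loc["Paleocene", "mean_proportion"] == pytest.approx(0.84)

    def test_rates_by_hand(self):
        bins = build_bins(toy_stage_table(), BinningConfig())
        rates = diversification_rate(bins, allow_missing_previous=True)
        # Paleocene: 42 new / (10 Ma x 44 standing in the Maastrichtian)
        assert rates.loc["Paleocene", "rate"] == pytest.approx(42 / (10.0 * 44))

    def test_frame_round_trip(self):
        bins = build_bins(toy_stage_table(), BinningConfig())
        frame = bins_to_frame(bins)
        assert frame.loc["Turonian-Coniacian", "stages"] == "Turonian+Coniacian"
        assert frame["duration_Ma"].sum() == pytest.approx(93.9 - 47.8)
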