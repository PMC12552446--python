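"""Raw-label parsing, intensity rules, capture statistics and epochs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camannotate.annotations import (INTENSITY_CLASSES, InvalidMETError,
                                     aggregate_to_epochs, annotate_table,
                                     assign_intensity, capture_stats,
                                     estimate_time_covered, is_codeable,
                                     parse_raw_label, summarize_study)


class TestParseRawLabel:
    @pytest.mark.parametrize("raw, prefixes, code, description", [
        ("occupation;interruption;13030 eating sitting",
         ("occupation", "interruption"), 13030, "eating sitting"),
        # 4-digit Compendium codes occur in real exports and are accepted
        ("5060 shopping miscellaneous", (), 5060, "shopping miscellaneous"),
        ("walking;5060 shopping miscellaneous", ("walking",), 5060,
         "shopping miscellaneous"),
        ("office wok/computer work general", (), None,
         "office wok/computer work general"),
        ("uncodeable", (), None, "uncodeable"),
        ("13030", (), 13030, ""),           # code-only terminal segment
        ("123456 too wide", (), None, "123456 too wide"),  # 6 digits: no code
    ])
    def test_decomposition(self, raw, prefixes, code, description):
        parsed = parse_raw_label(raw)
        assert parsed.prefixes == prefixes
        assert parsed.compendium_code == code
        assert parsed.description == description

    def test_code_width_recorded(self):
        assert parse_raw_label("13030 eating sitting").code_width == 5
        assert parse_raw_label("5060 shopping").code_width == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parse_raw_label("   ")

    @given(st.text(min_size=1).filter(lambda s: s.strip()))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_parsing_is_total(self, raw):
        parsed = parse_raw_label(raw)
        assert isinstance(parsed.description, str)
        assert (parsed.compendium_code is None) == (parsed.code_width is None)


class TestIsCodeable:
    @pytest.mark.parametrize("raw, expected", [
        ("uncodeable", False),
        ("Uncodeable  ", False),
        ("undefined", False),
        ("image dark/blurred/obscured", False),
        ("image  dark/blurred/obscured", False),   # whitespace normalised
        ("walking;17170 walking", True),
        ("leisure;uncodeable", False),             # segment-level match
        ("13030 eating sitting", True),
    ])
    def test_vocabulary(self, raw, expected):
        assert is_codeable(raw) is expected

    def test_custom_vocabulary(self):
        assert is_codeable("uncodeable", unknown_vocabulary=("nothing",))


class TestAssignIntensity:
    @pytest.mark.parametrize("met, posture, expected", [
        (1.5, "sitting", "SB"),      # SB boundary: <= 1.5 MET, sedentary posture
        (1.5, "lying", "SB"),
        (1.5, "reclining", "SB"),
        (1.5, "standing", "LIPA"),   # posture clause fails
        (1.6, "sitting", "LIPA"),    # above the SB MET bound
        (2.9, "sitting", "LIPA"),
        (2.99, "moving", "LIPA"),
        (3.0, "standing", "MVPA"),   # MVPA boundary: >= 3 MET
        (7.0, "sitting", "MVPA"),
        (0.9, "lying", "SB"),
    ])
    def test_truth_table(self, met, posture, expected):
        assert assign_intensity(met, posture) == expected

    def test_non_waking_is_sleep(self):
        assert assign_intensity(2.0, "sitting", waking=False) == "sleep"

    @pytest.mark.parametrize("met", [0.0, -1.0, float("nan"), None])
    def test_invalid_met_signalled(self, met):
        with pytest.raises(InvalidMETError):
            assign_intensity(met, "sitting")

    def test_unknown_posture_low_met_is_conservative_lipa(self):
        with pytest.warns(UserWarning):
            assert assign_intensity(1.2, "unknown") == "LIPA"

    @given(st.floats(min_value=0.1, max_value=20.0,
                     allow_nan=False, allow_infinity=False),
           st.sampled_from(["sitting", "lying", "reclining", "standing",
                            "moving"]))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_waking_classes_partition(self, met, posture):
        """Exactly one of SB/LIPA/MVPA for any valid waking input."""
        assert assign_intensity(met, posture) in INTENSITY_CLASSES

    @given(st.floats(min_value=1.5, max_value=3.0, exclude_min=True,
                     exclude_max=True, allow_nan=False),
           st.sampled_from(["sitting", "lying", "reclining", "standing"]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mid_met_never_sb(self, met, posture):
        assert assign_intensity(met, posture) == "LIPA"


class TestCaptureStats:
    def test_constant_spacing(self):
        stats = capture_stats([0, 24, 48, 72])
        assert stats.delta_t_median == 24

    def test_hand_enumerated_quartiles(self):
        # diffs {20, 40}: linear-interpolation median is 30
        stats = capture_stats([0, 20, 60])
        assert stats.delta_t_median == 30
        assert stats.delta_t_q1 == 25 and stats.delta_t_q3 == 35

    def test_degenerate_single_timestamp(self):
        stats = capture_stats([100.0])
        assert stats.delta_t_median is None
        assert len(stats.delta_t_values) == 0
        assert stats.n_images == 1

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            capture_stats([0, 10, 10])

    def test_stream_break_gap_excluded(self):
        # 5 h gap is a stream break, not a capture interval
        stats = capture_stats([0, 24, 48, 48 + 5 * 3600, 48 + 5 * 3600 + 24])
        assert len(stats.delta_t_values) == 3
        assert stats.delta_t_median == 24

    def test_datetime_timestamps(self):
        ts = pd.date_range("2024-01-01 08:00", periods=4, freq="24s", tz="UTC")
        assert capture_stats(ts.to_numpy()).delta_t_median == 24

    def test_quartiles_match_sorted_array_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(3, 1000))
            ts = np.cumsum(rng.uniform(1, 100, size=n))
            stats = capture_stats(ts, split_gap_s=np.inf)
            diffs = np.sort(np.diff(ts))

            def interp_quantile(sorted_vals, q):
                # linear interpolation between order statistics
                pos = q * (len(sorted_vals) - 1)
                lo, hi = int(np.floor(pos)), int(np.ceil(pos))
                frac = pos - lo
                return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

            assert stats.delta_t_q1 == pytest.approx(interp_quantile(diffs, 0.25))
            assert stats.delta_t_median == pytest.approx(interp_quantile(diffs, 0.50))
            assert stats.delta_t_q3 == pytest.approx(interp_quantile(diffs, 0.75))


class TestTimeCovered:
    def test_reported_study_values(self):
        """The coverage formula reproduces both printed study totals."""
        assert estimate_time_covered(231_837, 24).hours == 1546
        assert estimate_time_covered(46_184, 84).hours == 1078

    def test_exact_value_retained(self):
        est = estimate_time_covered(231_837, 24)
        assert est.hours_exact == pytest.approx(1545.58)

    def test_empty_study(self):
        assert estimate_time_covered(0, 24).hours == 0

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            estimate_time_covered(100, 0)

    def test_rounding_is_half_up(self):
        assert estimate_time_covered(1800, 3).hours == 2  # 1.5 h rounds up


class TestEpochAggregation:
    @staticmethod
    def frame(ts, labels, intensities, pid="A"):
        return pd.DataFrame({"participant_id": pid, "timestamp": ts,
                             "raw_label": labels, "intensity": intensities})

    def test_full_cover_single_activity(self):
        df = self.frame([0, 30, 60], ["x"] * 3, ["SB"] * 3)
        ep = aggregate_to_epochs(df, 60)
        assert ep.iloc[0]["intensity"] == "SB"
        assert ep.iloc[0]["support_fraction"] == 1.0

    def test_majority_duration_wins(self):
        # SB run covers 40 s, LIPA run 19 s of the first epoch
        df = self.frame([0, 40, 41, 60], ["a", "a", "b", "b"],
                        ["SB", "SB", "LIPA", "LIPA"])
        ep = aggregate_to_epochs(df, 60)
        assert ep.iloc[0]["intensity"] == "SB"

    def test_uncovered_epoch_is_unknown(self):
        # runs [0,40] and [120,160]; epoch [60,120) has zero labelled cover
        df = self.frame([0, 40, 120, 160], ["a", "a", "b", "b"],
                        ["SB", "SB", "LIPA", "LIPA"])
        ep = aggregate_to_epochs(df, 60)
        assert ep.iloc[1]["intensity"] == "unknown"
        assert ep.iloc[1]["support_fraction"] == 0.0

    def test_tie_breaks_to_higher_intensity(self):
        # SB run [0, 30] and MVPA run [30, 60]: exact 30 s tie
        df = self.frame([0, 30, 30, 60], ["a", "a", "b", "b"],
                        ["SB", "SB", "MVPA", "MVPA"])
        ep = aggregate_to_epochs(df, 60)
        assert ep.iloc[0]["intensity"] == "MVPA"

    def test_unknown_intensity_runs_do_not_cover(self):
        df = self.frame([0, 60], ["u", "u"], ["unknown", "unknown"])
        ep = aggregate_to_epochs(df, 60)
        assert (ep["intensity"] == "unknown").all()

    def test_time_conservation(self):
        """Sum of support_fraction x epoch_length equals total labelled
        run time (runs always lie inside the epoch grid)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(5, 80))
            ts = np.cumsum(rng.uniform(5, 60, size=n))
            labels = rng.choice(["a", "b", "c"], size=n)
            intensity = {"a": "SB", "b": "LIPA", "c": "MVPA"}
            df = self.frame(ts, labels, [intensity[l] for l in labels])
            L = float(rng.uniform(30, 200))
            ep = aggregate_to_epochs(df, L)
            # independent tally: run extents from label change points
            total = 0.0
            start = 0
            for i in range(1, n + 1):
                if i == n or labels[i] != labels[i - 1]:
                    total += ts[i - 1] - ts[start]
                    start = i
            assert (ep["support_fraction"] * L).sum() == pytest.approx(total)


class TestStudySummary:
    def test_printed_fraction_shape(self):
        # 3 labelled of 4 images -> 75% labelled, 25.0% unknown
        df = pd.DataFrame({
            "participant_id": ["A"] * 4,
            "raw_label": ["13030 eating sitting", "uncodeable",
                          "5060 shopping", "5060 shopping"],
        })
        s = summarize_study(df)
        assert s["n_images"] == 4 and s["n_labelled"] == 3
        assert s["pct_labelled"] == 75 and s["pct_unknown"] == 25.0
        assert s["n_unique_labels"] == 2

    def test_empty_study(self):
        s = summarize_study(pd.DataFrame(columns=["participant_id",
                                                  "raw_label"]))
        assert s["n_images"] == 0 and s["n_labelled"] == 0

    def test_class_count_medians(self):
        df = pd.DataFrame({
            "participant_id": ["A"] * 3 + ["B"] * 3,
            "raw_label": ["x"] * 6,
            "intensity": ["SB", "SB", "LIPA", "SB", "MVPA", "MVPA"],
        })
        s = summarize_study(df)
        med = s["median_instances_per_participant"]
        assert med["SB"] == 1.5 and med["LIPA"] == 0.5 and med["MVPA"] == 1.0


class TestAnnotateTable:
    def test_met_table_lookup_and_intensity(self):
        df = pd.DataFrame({
            "participant_id": ["A", "A", "A"],
            "timestamp": [0, 24, 48],
            "raw_label": ["occupation;13030 eating sitting",
                          "17170 walking briskly", "uncodeable"],
        })
        met_table = {13030: {"met": 1.5, "posture": "sitting"},
                     17170: {"met": 3.5, "posture": "moving"}}
        out = annotate_table(df, met_table)
        assert list(out["intensity"]) == ["SB", "MVPA", "unknown"]
        assert out["codeable"].tolist() == [True, True, False]
        assert len(out) == len(df)

    def test_posture_falls_back_to_description_tokens(self):
        df = pd.DataFrame({"participant_id": ["A"], "timestamp": [0],
                           "raw_label": ["13030 eating sitting"],
                           "met": [1.5]})
        out = annotate_table(df)
        assert out["posture"].iloc[0] == "sitting"
        assert out["intensity"].iloc[0] == "SB"
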