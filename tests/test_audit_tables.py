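"""Bin schemes, percent rendering, and table construction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from powergap.audit_tables import (
    AuditTable,
    FollowupBin,
    FollowupBin9,
    MeanPctBin,
    RatioBin,
    bin_followup,
    bin_mean_pct,
    bin_ratio,
    crosstab,
    frequency_table,
    median_iqr,
    render_percent,
)


class TestBinFollowup:
    @pytest.mark.parametrize(
        "days, expected",
        [
            (None, FollowupBin.NOT_APPLICABLE),
            (0.0, FollowupBin.UNDER_3M),
            (90.0, FollowupBin.UNDER_3M),
            (92.0, FollowupBin.M3_TO_6M),
            (183.0, FollowupBin.M6_TO_12M),
            (365.0, FollowupBin.M6_TO_12M),  # 365 d < 365.25 d: within 12 months
            (730.0, FollowupBin.OVER_12M),
        ],
    )
    def test_coarse_scheme(self, days, expected):
        assert bin_followup(days, "coarse") is expected

    @pytest.mark.parametrize(
        "days, expected",
        [
            (None, FollowupBin9.NOT_APPLICABLE),
            (1.0, FollowupBin9.LE_1D),
            (5.0, FollowupBin9.D1_TO_1W),
            (20.0, FollowupBin9.W1_TO_1M),
            (60.0, FollowupBin9.M1_TO_3M),
            (300.0, FollowupBin9.M3_TO_1Y),
            (800.0, FollowupBin9.Y1_TO_3Y),
            (2000.0, FollowupBin9.Y3_TO_10Y),
            (5000.0, FollowupBin9.OVER_10Y),
        ],
    )
    def test_nine_category_scheme(self, days, expected):
        assert bin_followup(days, "nine") is expected

    def test_negative_followup_rejected(self):
        with pytest.raises(ValueError):
            bin_followup(-1.0)

    @given(days=st.one_of(st.none(), st.floats(0.0, 10_000.0)))
    def test_both_schemes_partition_the_axis(self, days):
        assert bin_followup(days, "coarse") in FollowupBin
        assert bin_followup(days, "nine") in FollowupBin9


class TestBinMeanPct:
    @pytest.mark.parametrize(
        "pct, expected",
        [
            (60.0, MeanPctBin.LE_60),
            (75.0, MeanPctBin.GT60_LE75),
            (85.0, MeanPctBin.GT75_LE85),
            (87.3, MeanPctBin.GT85_LT90),
            (90.0, MeanPctBin.GE_90),
            (100.0, MeanPctBin.GE_90),
        ],
    )
    def test_boundaries(self, pct, expected):
        assert bin_mean_pct(pct) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_mean_pct(101.0)


class TestBinRatio:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (0.41, RatioBin.LT_0_5),
            (0.5, RatioBin.R0_5_TO_1),
            (1.0, RatioBin.R1_TO_1_5),
            (1.5, RatioBin.GT_1_5),
            (2.3, RatioBin.GT_1_5),
        ],
    )
    def test_half_open_boundaries(self, ratio, expected):
        assert bin_ratio(ratio) is expected

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            bin_ratio(-0.1)


class TestRenderPercent:
    @pytest.mark.parametrize(
        "count, denom, expected",
        [
            (108, 264, "41 %"),
            (148, 264, "56 %"),
            (116, 264, "44 %"),
            (43, 264, "16 %"),
            (23, 264, "9 %"),
            (15, 264, "6 %"),
            (38, 107, "36 %"),
            (1, 264, "0.4 %"),
            (0, 264, "0 %"),
            (65, 113, "58 %"),
        ],
    )
    def test_printed_pairs(self, count, denom, expected):
        assert render_percent(count, denom) == expected

    def test_half_even_mode_differs_at_ties(self):
        assert render_percent(1, 8, "half-away") == "13 %"  # 12.5
        assert render_percent(1, 8, "half-even") == "12 %"


class TestMedianIqr:
    def test_linear_interpolation(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_constant_and_singleton(self):
        assert median_iqr([7.0] * 9) == (7.0, 7.0, 7.0)
        assert median_iqr([4.2]) == (4.2, 4.2, 4.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestFrequencyTable:
    def test_single_class_registry_is_100_percent(self):
        table = frequency_table(["a", "a", "a"], classifier=lambda x: x)
        assert table.cell(0, 0) == "3 (100 %)"

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            frequency_table([], classifier=lambda x: x)

    def test_multivalued_classifier_counts_each_label(self):
        items = [{"x", "y"}, {"x"}, set()]
        table = frequency_table(
            items, classifier=lambda s: sorted(s), denominator=3,
            class_order=["x", "y"],
        )
        assert table.counts_frame().loc["x"].item() == 2
        assert table.counts_frame().loc["y"].item() == 1

    def test_brute_force_tally_oracle(self, default_registry):
        """Table counts must equal a naive per-record loop on ~500 records."""
        from powergap import SimConfig, generate_registry

        records, _ = generate_registry(SimConfig(n_trials=500, seed=11))
        table = frequency_table(
            records,
            classifier=lambda r: r.power.rationale if r.power else None,
            denominator=len(records),
        )
        naive: dict = {}
        for record in records:
            key = record.power.rationale if record.power else None
            if key is None:
                continue
            naive[key.value] = naive.get(key.value, 0) + 1
        frame = table.counts_frame()
        for label, count in naive.items():
            assert frame.loc[label].item() == count
        assert int(frame.to_numpy().sum()) == sum(naive.values())


class TestCrosstab:
    def test_over_90_row_renders_73_percent(self):
        """Row counts (0, 0, 2, 2, 11) with row-wise percents put the
        longest-follow-up cell at 11 (73 %)."""
        table = AuditTable(
            title="t",
            row_labels=["Over 90 %"],
            col_labels=["NA", "<3m", "3-6m", "6-12m", ">12m"],
            counts=np.array([[0, 0, 2, 2, 11]]),
            percent_axis="row",
        )
        assert table.cell(0, 4) == "11 (73 %)"
        assert table.cell(0, 2) == "2 (13 %)"

    def test_total_column_uses_grand_denominator(self):
        # column-percent body with a margin column scored against the grand total
        counts = np.array([[65, 0], [48, 0]])
        counts[:, 1] = counts[:, 0]
        table = AuditTable(
            title="t",
            row_labels=["< 0.5", "rest"],
            col_labels=["only", "Total"],
            counts=counts,
            percent_axis="col",
            total_col_index=1,
        )
        assert table.cell(0, 1) == "65 (58 %)"

    def test_single_record_is_100_percent(self):
        table = crosstab([("a", "x")], lambda p: p[0], lambda p: p[1],
                         percent_axis="row")
        assert table.cell(0, 0) == "1 (100 %)"

    def test_transpose_property(self, default_registry):
        records, _ = default_registry
        row_c = lambda r: r.power.rationale.value if r.power else None  # noqa: E731
        col_c = lambda r: bin_followup(r.followup_days).value  # noqa: E731
        ab = crosstab(records, row_c, col_c)
        ba = crosstab(records, col_c, row_c)
        assert np.array_equal(ab.counts, ba.counts.T)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            crosstab([], lambda x: x, lambda x: x)

    def test_brute_force_oracle_on_large_registry(self, large_registry):
        """Cross-tab cells equal a naive double loop on a 2,000-trial registry."""
        records, _ = large_registry
        row_c = lambda r: r.power.rationale.value if r.power else None  # noqa: E731
        col_c = lambda r: bin_followup(r.followup_days).value  # noqa: E731
        table = crosstab(records, row_c, col_c)
        for i, row_label in enumerate(table.row_labels):
            for j, col_label in enumerate(table.col_labels):
                naive = sum(
                    1
                    for r in records
                    if row_c(r) == row_label and col_c(r) == col_label
                )
                assert table.counts[i, j] == naive
        assert int(table.counts.sum()) == len(records)
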