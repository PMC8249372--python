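import numpy as np
import pandas as pd
import pytest

from pomstat import (
    BIN_LABELS,
    EqsStandard,
    assess,
    bin_pom,
    classify_indicator,
    classify_water_body,
    round_sig,
    status_pom,
    summarize,
)
from pomstat.censored_stats import SeriesStats

from conftest import make_series


def cls_of(indicator, mean, maximum, aa=0.006, mac=0.12):
    return classify_indicator(
        SeriesStats(mean, maximum, 0.1, 0.1, 6, 0),
        EqsStandard(indicator, aa, mac),
        indicator_id=indicator,
    )


class TestBinning:
    @pytest.mark.parametrize(
        "p, label",
        [
            (0.0, "<0,0.1>"),
            (0.05, "<0,0.1>"),
            (0.1, "<0,0.1>"),          # first interval is closed above
            (0.1 + 1e-12, "(0.1,0.3>"),
            (0.3, "(0.1,0.3>"),
            (0.3 + 1e-12, "(0.3,0.5>"),
            (0.47, "(0.3,0.5>"),
            (0.5, "(0.3,0.5>"),
            (0.5 + 1e-12, "(0.5,1>"),
            (1.0, "(0.5,1>"),
        ],
    )
    def test_boundaries(self, p, label):
        assert bin_pom(p) == label

    def test_partition_of_unit_interval(self):
        for p in np.linspace(0, 1, 1001):
            assert bin_pom(float(p)) in BIN_LABELS

    @pytest.mark.parametrize("p", [-0.01, 1.01, float("nan")])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            bin_pom(p)


class TestStatusPom:
    def test_good_status_takes_max_over_all_indicators(self):
        wb = classify_water_body(
            "A", 2017, [cls_of(i, 0.001, 0.01) for i in "abc"]
        )
        res = status_pom(wb, {"a": 0.81, "b": 0.16, "c": 0.47})
        assert res.level4 == 0.81
        assert res.decisive_indicator == "a"
        assert res.bin == "(0.5,1>"

    def test_below_good_ignores_good_indicators(self):
        wb = classify_water_body(
            "A", 2017, [cls_of("d", 0.01, 0.01), cls_of("e", 0.001, 0.01)]
        )
        assert wb.decisive == frozenset({"d"})
        res = status_pom(wb, {"d": 0.2, "e": 0.9})
        assert res.level4 == 0.2 and res.decisive_indicator == "d"

    def test_singleton(self):
        wb = classify_water_body("A", 2017, [cls_of("a", 0.001, 0.01)])
        res = status_pom(wb, {"a": 0.33})
        assert res.level4 == 0.33

    def test_tie_resolves_lexicographically(self):
        wb = classify_water_body(
            "A", 2017, [cls_of(i, 0.001, 0.01) for i in ("z", "m", "a")]
        )
        res = status_pom(wb, {"z": 0.4, "m": 0.4, "a": 0.4})
        assert res.decisive_indicator == "a"

    def test_missing_level3_entry_errors(self):
        wb = classify_water_body("A", 2017, [cls_of("a", 0.001, 0.01)])
        with pytest.raises(ValueError, match="missing"):
            status_pom(wb, {})

    def test_level4_dominates_and_ignores_non_argmax(self):
        wb3 = classify_water_body(
            "A", 2017, [cls_of(i, 0.001, 0.01) for i in "abc"]
        )
        level3 = {"a": 0.1, "b": 0.45, "c": 0.2}
        res = status_pom(wb3, level3)
        assert all(res.level4 >= p for p in level3.values())
        wb2 = classify_water_body(
            "A", 2017, [cls_of(i, 0.001, 0.01) for i in "ab"]
        )
        assert status_pom(wb2, {"a": 0.1, "b": 0.45}).level4 == res.level4

    def test_nan_entries_are_skipped(self):
        wb = classify_water_body(
            "A", 2017, [cls_of(i, 0.001, 0.01) for i in "ab"]
        )
        res = status_pom(wb, {"a": float("nan"), "b": 0.2})
        assert res.level4 == 0.2


class TestSummarize:
    def frame(self, level4s, **extra):
        n = len(level4s)
        base = {
            "wb_id": [f"W{i}" for i in range(n)],
            "year": [2017] * n,
            "stdev_variant": ["modified"] * n,
            "status": ["good"] * n,
            "pom_level4": level4s,
            "bin": [bin_pom(p) for p in level4s],
        }
        base.update(extra)
        return pd.DataFrame(base)

    def test_uniform_spread(self):
        summary = summarize(self.frame([0.05, 0.2, 0.4, 0.7]))
        assert list(summary["pct"]) == [25.0] * 4
        assert summary["pct"].sum() == pytest.approx(100.0)

    def test_single_bin(self):
        summary = summarize(self.frame([0.05, 0.06, 0.07]))
        by_bin = dict(zip(summary["bin"], summary["pct"]))
        assert by_bin["<0,0.1>"] == 100.0
        assert sum(by_bin.values()) == pytest.approx(100.0)

    def test_permutation_invariance_and_total(self):
        values = [0.02, 0.15, 0.35, 0.8, 0.45, 0.09]
        a = summarize(self.frame(values))
        b = summarize(self.frame(values[::-1]))
        pd.testing.assert_frame_equal(
            a.sort_values("bin").reset_index(drop=True),
            b.sort_values("bin").reset_index(drop=True),
        )
        for _, grp in a.groupby(["stdev_variant", "status"], observed=True):
            assert grp["pct"].sum() == pytest.approx(100.0, abs=0.1)


class TestAssessPipeline:
    def test_end_to_end_both_variants(self, benzo_eqs, fluoranthene_eqs,
                                      endosulfan_eqs):
        series = [
            make_series(["<0.00005", "0.0008", "0.00008", "<0.00005",
                         "<0.00005", "<0.00005"], wb="L1",
                        indicator="benzo(a)pyrene"),
            make_series(["<0.001"] * 6, wb="L1", indicator="endosulfan"),
            make_series(["0.009", "0.003", "<0.001", "<0.001", "0.007",
                         "<0.001"], wb="L2", indicator="fluoranthene"),
            # a below-good water body via the mean criterion
            make_series(["0.02", "0.03", "0.01", "0.05"], wb="L3",
                        indicator="fluoranthene"),
        ]
        wb, ind = assess(
            series, [benzo_eqs, fluoranthene_eqs, endosulfan_eqs],
            stdev_variants=("conventional", "modified"),
        )
        assert len(wb) == 6  # 3 water bodies x 2 variants
        assert set(ind["stdev_variant"]) == {"conventional", "modified"}
        l1_conv = wb[(wb.wb_id == "L1") & (wb.stdev_variant == "conventional")]
        assert l1_conv.status.iloc[0] == "good"
        # under the conventional stdev the all-censored endosulfan has P_om 0,
        # so the PAH drives Level 4
        assert l1_conv.decisive_indicator.iloc[0] == "benzo(a)pyrene"
        l3 = wb[wb.wb_id == "L3"]
        assert set(l3.status) == {"below_good"}
        assert set(l3.decisive_indicator) == {"fluoranthene"}
        # below-good via a clearly quantified exceedance: both variants agree
        poms = l3.pom_level4.to_numpy()
        assert poms[0] == pytest.approx(poms[1], rel=1e-9)

    def test_indicator_without_eqs_is_skipped(self, fluoranthene_eqs):
        series = [
            make_series(["0.001"] * 3, wb="A", indicator="fluoranthene"),
            make_series(["0.5"] * 3, wb="A", indicator="unregulated"),
        ]
        wb, ind = assess(series, [fluoranthene_eqs])
        assert set(ind["indicator"]) == {"fluoranthene"}
        assert wb.status.iloc[0] == "good"

    def test_sum_group_assessed_through_group(self, fluoranthene_eqs):
        group = EqsStandard(
            "cyclodienes", 0.01, 0.02, is_sum_group=True,
            members=("aldrin", "dieldrin", "endrin", "isodrin"),
        )
        series = [
            make_series(["<0.002"] * 4, wb="A", indicator="aldrin"),
            make_series(["<0.002"] * 4, wb="A", indicator="dieldrin"),
        ]
        wb, ind = assess(series, [fluoranthene_eqs, group])
        assert list(ind["indicator"]) == ["cyclodienes"]
        assert ind["mean"].iloc[0] == pytest.approx(0.002, rel=1e-12)


def test_round_sig_matches_display_convention():
    assert round_sig(0.000322) == 0.00032
    assert round_sig(0.0037338) == 0.0037
    assert round_sig(0.003980) == 0.004
    assert round_sig(0.0) == 0.0
    assert round_sig(1.6333e-4) == 1.6e-4
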