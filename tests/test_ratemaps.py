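import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ancrecomb.ratemaps import (
    RecombinationMap,
    assign_quartiles,
    fill_desert_zero,
    make_windows,
    map_rates_to_windows,
    sliding_average,
)


def track(rows, species="sp"):
    return RecombinationMap(species, pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"]))


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (4_500_000, [(0, 1_500_000), (1_500_000, 3_000_000), (3_000_000, 4_500_000)]),
            (4_000_000, [(0, 1_500_000), (1_500_000, 3_000_000), (3_000_000, 4_000_000)]),
            (1_000_000, [(0, 1_000_000)]),
        ],
    )
    def test_tiling_with_truncated_terminal_window(self, length, expected):
        win = make_windows({"chr1": length})
        assert list(zip(win["start"], win["end"])) == expected

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 0})


class TestSlidingAverage:
    def test_constant_rate_gives_constant_blocks(self):
        rows = [("chr1", s, s + 50_000, 3.5) for s in range(0, 5_000_000, 50_000)]
        out = sliding_average(track(rows))
        assert np.allclose(out.windows["rate"], 3.5)

    def test_single_full_length_interval_propagates(self):
        out = sliding_average(track([("chr1", 0, 6_000_000, 5.0)]))
        assert np.allclose(out.windows["rate"], 5.0)
        assert out.windows["end"].max() == 6_000_000

    def test_block_means_match_bruteforce_over_tiles(self):
        # 50 kb tiles carrying 1, 2, 3, ...; oracle: enumerate tiles per block
        n = 120
        rows = [("chr1", i * 50_000, (i + 1) * 50_000, float(i + 1)) for i in range(n)]
        out = sliding_average(track(rows), block=2_000_000, step=50_000)
        length = n * 50_000
        for row in out.windows.itertuples(index=False):
            overlapped = [
                v for (c, s, e, v) in rows if s < row.end and e > row.start
            ]
            assert row.rate == pytest.approx(np.mean(overlapped))
        assert out.windows["start"].tolist() == list(range(0, length, 50_000))

    def test_block_equal_to_chromosome_reduces_to_global_mean(self):
        rows = [("chr1", i * 50_000, (i + 1) * 50_000, float(i)) for i in range(40)]
        out = sliding_average(track(rows), block=2_000_000, step=2_000_000)
        assert len(out.windows) == 1
        assert out.windows["rate"].iloc[0] == pytest.approx(np.mean([r[3] for r in rows]))

    def test_empty_track_gives_empty_output(self):
        out = sliding_average(track([]))
        assert len(out.windows) == 0


class TestMapRatesToWindows:
    def test_uniform_source_propagates(self):
        rmap = track([("chr1", 0, 1_000_000, 2.0), ("chr1", 1_000_000, 2_000_000, 2.0)])
        win = make_windows({"chr1": 2_000_000}, size=500_000)
        out = map_rates_to_windows(rmap, win)
        assert np.allclose(out.windows["rate"], 2.0)

    def test_window_without_data_is_missing_and_absent_chrom_warns(self):
        rmap = track([("chr1", 0, 1_000_000, 2.0)])
        win = pd.DataFrame(
            [("chr1", 0, 1_000_000), ("chr1", 2_000_000, 3_000_000), ("chr2", 0, 1_000_000)],
            columns=["chrom", "start", "end"],
        )
        with pytest.warns(UserWarning, match="chr2"):
            out = map_rates_to_windows(rmap, win)
        by_key = {(r.chrom, r.start): r.rate for r in out.windows.itertuples(index=False)}
        assert by_key[("chr1", 0)] == 2.0
        assert np.isnan(by_key[("chr1", 2_000_000)])
        assert np.isnan(by_key[("chr2", 0)])

    def test_unweighted_vs_length_weighted_mean(self):
        # one short and one long interval: unweighted mean ignores lengths
        rmap = track([("chr1", 0, 100_000, 2.0), ("chr1", 100_000, 1_000_000, 4.0)])
        win = pd.DataFrame([("chr1", 0, 1_000_000)], columns=["chrom", "start", "end"])
        unweighted = map_rates_to_windows(rmap, win).windows["rate"].iloc[0]
        weighted = map_rates_to_windows(rmap, win, length_weighted=True).windows["rate"].iloc[0]
        assert unweighted == pytest.approx(3.0)
        assert weighted == pytest.approx((2.0 * 100_000 + 4.0 * 900_000) / 1_000_000)

    def test_idempotent_when_source_equals_windows(self):
        win = make_windows({"chr1": 4_500_000})
        rng = np.random.default_rng(0)
        rmap = RecombinationMap("sp", win.assign(rate=rng.uniform(0, 5, len(win))))
        out = map_rates_to_windows(rmap, win)
        pd.testing.assert_frame_equal(out.windows, rmap.windows)


class TestFillDesertZero:
    def test_rules(self):
        rmap = track(
            [("chrX", 0, 1_000_000, np.nan), ("chrX", 1_000_000, 2_000_000, 7.0),
             ("chrX", 3_000_000, 4_000_000, np.nan)]
        )
        deserts = pd.DataFrame([("chrX", 0, 2_000_000)], columns=["chrom", "start", "end"])
        out = fill_desert_zero(rmap, deserts).windows
        assert out["rate"].iloc[0] == 0.0  # missing inside desert -> 0
        assert out["rate"].iloc[1] == 7.0  # data inside desert untouched
        assert np.isnan(out["rate"].iloc[2])  # missing outside desert stays missing


class TestAssignQuartiles:
    def test_equal_split_of_distinct_rates(self):
        rows = [("chr1", i * 10, i * 10 + 10, float(i + 1)) for i in range(8)]
        cats = assign_quartiles(track(rows)).entries["category"]
        assert list(cats) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_all_equal_rates_warns_and_uses_coordinate_tiebreak(self):
        rows = [("chr1", i * 10, i * 10 + 10, 1.0) for i in range(8)]
        with pytest.warns(UserWarning, match="tie-break"):
            cats = assign_quartiles(track(rows)).entries["category"]
        # descending sort ties broken by coordinate: earliest coords -> highest group
        assert list(cats) == ["Q4", "Q4", "Q3", "Q3", "Q2", "Q2", "Q1", "Q1"]

    def test_tie_at_boundary_matches_stable_sort_oracle(self):
        rates = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 7.0, 9.0, 10.0]
        rows = [("chr1", i * 10, i * 10 + 10, r) for i, r in enumerate(rates)]
        cats = assign_quartiles(track(rows)).entries["category"].tolist()
        # oracle: stable descending sort with coordinate tie-break, top groups bigger
        order = sorted(range(10), key=lambda i: (-rates[i], i))
        sizes = {"Q4": 3, "Q3": 3, "Q2": 2, "Q1": 2}
        expected = [None] * 10
        pos = 0
        for cat in ("Q4", "Q3", "Q2", "Q1"):
            for _ in range(sizes[cat]):
                expected[order[pos]] = cat
                pos += 1
        assert cats == expected

    def test_too_few_rated_windows_rejected(self):
        rows = [("chr1", 0, 10, 1.0), ("chr1", 10, 20, 2.0), ("chr1", 20, 30, np.nan)]
        with pytest.raises(ValueError, match=">= 4"):
            assign_quartiles(track(rows))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=4, max_value=97), st.randoms(use_true_random=False))
    def test_quartile_balance_property(self, n, rnd):
        rates = [rnd.uniform(0, 10) for _ in range(n)]
        rows = [("chr1", i * 10, i * 10 + 10, r) for i, r in enumerate(rates)]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            counts = assign_quartiles(track(rows)).counts()
        assert sum(counts.values()) == n
        for c in counts.values():
            assert abs(c - n / 4) <= 1
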