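import itertools

import numpy as np
import pandas as pd
import pytest

from ancrecomb.conserved import (
    ConservedCall,
    call_conserved_regions,
    classify_region,
    consensus_call,
    merge_calls,
    resolve_overlaps,
)
from ancrecomb.intervals import merge_adjacent
from ancrecomb.ratemaps import QuartileTrack
from ancrecomb.synteny import identity_map

CATS = ("Q1", "Q2", "Q3", "Q4")


def call(cls, start, end, support=3, chrom="chr1"):
    return ConservedCall(cls, chrom, start, end, support)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "cats, expected",
        [
            (["Q1", "Q2", "Q1"], "low"),
            (["Q4", "Q3", "Q3", "Q4"], "high"),
            (["Q1", "Q1", "Q4"], "low"),
            (["Q1", "Q4"], "none"),
            (["Q2", "Q2"], "low"),  # no extreme needed: adjacent category alone suffices
            ([None, None], "none"),
        ],
    )
    def test_rule_examples(self, cats, expected):
        assert classify_region(cats) == expected

    def test_matches_exhaustive_enumeration_up_to_six_windows(self):
        # independent oracle: count low/high-side windows directly
        for size in range(1, 7):
            for combo in itertools.product(CATS, repeat=size):
                n_low = sum(c in ("Q1", "Q2") for c in combo)
                n_high = size - n_low
                expected = "low" if n_low > n_high else ("high" if n_high > n_low else "none")
                assert classify_region(list(combo)) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            classify_region(["Q5"])


class TestConsensusCall:
    def test_three_of_four_agreement(self):
        out = consensus_call(
            {"a": "low", "b": "low", "c": "low", "d": "high"}, ("chr1", 0, 10)
        )
        assert out is not None and out.region_class == "ALR" and out.support == 3

    def test_split_vote_gives_no_call(self):
        assert consensus_call({"a": "low", "b": "low", "c": "high", "d": "high"}, ("chr1", 0, 10)) is None

    def test_unanimous_support_four(self):
        out = consensus_call({s: "low" for s in "abcd"}, ("chr1", 0, 10))
        assert out.support == 4 and out.region_class == "ALR"

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError, match="species"):
            consensus_call({"a": "low", "b": "low"}, ("chr1", 0, 10))


class TestMergeCalls:
    def test_gap_within_megabase_merges(self):
        out = merge_calls([call("ALR", 0, 2_000_000), call("ALR", 2_500_000, 4_000_000)])
        assert [(c.start, c.end) for c in out] == [(0, 4_000_000)]

    def test_gap_beyond_megabase_stays_separate(self):
        out = merge_calls([call("ALR", 0, 2_000_000), call("ALR", 3_300_000, 4_000_000)])
        assert len(out) == 2

    def test_mixed_class_input_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            merge_calls([call("ALR", 0, 10), call("AHR", 20, 30)])

    def test_matches_bruteforce_union_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            starts = rng.integers(0, 50_000_000, size=n)
            calls = [call("AHR", int(s), int(s + rng.integers(1, 3_000_000))) for s in starts]
            gap = int(rng.integers(0, 2_000_000))
            merged = merge_calls(calls, max_gap=gap)
            expected = merge_adjacent([(c.start, c.end) for c in calls], max_gap=gap)
            assert [(c.start, c.end) for c in merged] == expected
            again = merge_calls(merged, max_gap=gap)
            assert [(c.start, c.end) for c in again] == expected
            # supports propagate as the max of constituents
            assert all(m.support == max(c.support for c in calls if
                                        m.start <= c.start and c.end <= m.end) for m in merged)


class TestResolveOverlaps:
    def test_partial_overlap_cut_at_midpoint(self):
        alr, ahr, events = resolve_overlaps([call("ALR", 0, 3_000_000)], [call("AHR", 2_000_000, 5_000_000)])
        assert (alr[0].start, alr[0].end) == (0, 2_500_000)
        assert (ahr[0].start, ahr[0].end) == (2_500_000, 5_000_000)
        assert events

    def test_disjoint_inputs_unchanged(self):
        alr, ahr, events = resolve_overlaps([call("ALR", 0, 1_000_000)], [call("AHR", 2_000_000, 3_000_000)])
        assert (alr[0].start, alr[0].end) == (0, 1_000_000)
        assert (ahr[0].start, ahr[0].end) == (2_000_000, 3_000_000)
        assert events == []

    def test_contained_call_dropped_and_logged(self):
        alr, ahr, events = resolve_overlaps([call("ALR", 0, 3_000_000)], [call("AHR", 1_000_000, 2_000_000)])
        assert ahr == []
        assert (alr[0].start, alr[0].end) == (0, 3_000_000)
        assert any("contained" in e for e in events)

    def test_random_sets_end_mutually_disjoint(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            def mk(cls):
                raw = [call(cls, int(s), int(s + rng.integers(1, 2_000_000)))
                       for s in rng.integers(0, 30_000_000, size=rng.integers(1, 6))]
                return merge_calls(raw, max_gap=0)
            alr, ahr = mk("ALR"), mk("AHR")
            out_alr, out_ahr, _ = resolve_overlaps(alr, ahr)
            for a in out_alr:
                for h in out_ahr:
                    assert min(a.end, h.end) <= max(a.start, h.start)


class TestCallConservedRegions:
    def _identical_tracks(self):
        # 10 windows: planted cold run at windows 4-5, everything else spread
        cats = ["Q3", "Q4", "Q2", "Q2", "Q1", "Q1", "Q2", "Q3", "Q4", "Q3"]
        entries = pd.DataFrame(
            [("chr1", i * 1_500_000, (i + 1) * 1_500_000, c) for i, c in enumerate(cats)],
            columns=["chrom", "start", "end", "category"],
        )
        return {f"sp{i}": QuartileTrack(f"sp{i}", entries.copy()) for i in range(1, 5)}

    def test_identity_synteny_planted_run_called_at_full_support(self):
        tracks = self._identical_tracks()
        ident = identity_map({"chr1": 15_000_000})
        ref_to = {sp: ident for sp in tracks if sp != "sp1"}
        alr, ahr, _ = call_conserved_regions(tracks, "sp1", ref_to)
        assert [(c.start, c.end, c.support) for c in alr] == [(6_000_000, 9_000_000, 4)]
        assert ahr == []  # no Q4 run of length >= 2

    def test_species_without_synteny_counts_as_none(self):
        tracks = self._identical_tracks()
        ident = identity_map({"chr1": 15_000_000})
        ref_to = {"sp2": ident, "sp3": ident}  # sp4 has no map
        alr, _, log = call_conserved_regions(tracks, "sp1", ref_to)
        assert [(c.start, c.end, c.support) for c in alr] == [(6_000_000, 9_000_000, 3)]
        assert any("no synteny map" in line for line in log)

    def test_final_call_sets_are_disjoint_and_merged(self, scenario):
        for calls in (scenario.alr, scenario.ahr):
            ordered = sorted(calls, key=lambda c: (c.chrom, c.start))
            for a, b in zip(ordered, ordered[1:]):
                if a.chrom == b.chrom:
                    assert b.start - a.end > 1_000_000  # no same-class gap <= merge gap
        for a in scenario.alr:
            for h in scenario.ahr:
                if a.chrom == h.chrom:
                    assert min(a.end, h.end) <= max(a.start, h.start)
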