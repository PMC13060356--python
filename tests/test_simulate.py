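import warnings

import numpy as np
import pandas as pd
import pytest

import ancrecomb as ar
from ancrecomb.ratemaps import assign_quartiles, make_windows, map_rates_to_windows
from ancrecomb.simulate import (
    SimConfig,
    apply_fission,
    apply_fusion,
    apply_inversion,
    simulate_alignment_pair,
    simulate_genes_and_pathways,
    simulate_karyotypes,
    simulate_recombination_landscape,
)

TREE = "((t1:0.1,t2:0.1):0.05,(t3:0.08,t4:0.12):0.05);"


class TestKaryotypeOps:
    def test_fission_splits_chromosome_at_breakpoint(self):
        chroms = [[("ANC1", 0, 100_000_000, "+")]]
        apply_fission(chroms, 0, 40_000_000)
        assert chroms == [
            [("ANC1", 0, 40_000_000, "+")],
            [("ANC1", 40_000_000, 100_000_000, "+")],
        ]

    def test_fusion_concatenates_and_flip_reverses(self):
        chroms = [[("A", 0, 10, "+")], [("B", 0, 20, "+")]]
        apply_fusion(chroms, 0, 1, flip_second=True)
        assert chroms == [[("A", 0, 10, "+"), ("B", 0, 20, "-")]]

    def test_inversion_reverses_segment_order_and_strand(self):
        chroms = [[("A", 0, 30, "+")]]
        apply_inversion(chroms, 0, 10, 20)
        assert chroms == [[("A", 0, 10, "+"), ("A", 10, 20, "-"), ("A", 20, 30, "+")]]


class TestSimulateKaryotypes:
    def test_no_rearrangements_gives_identity_synteny(self):
        cfg = SimConfig(seed=0, n_fissions=0, n_fusions=0, n_inversions=0)
        sim = simulate_karyotypes(cfg)
        anc = dict(cfg.ancestral_chromosomes)
        for g in sim.species:
            assert sorted(g.chrom_sizes.values()) == sorted(anc.values())
            for b in g.to_ancestor.blocks:
                assert b.strand == "+"
                assert (b.src_start, b.src_end) == (b.dst_start, b.dst_end)
                assert b.src_end - b.src_start == anc[b.dst_chrom]

    def test_same_seed_gives_identical_block_tables_and_truth(self):
        a = simulate_karyotypes(SimConfig(seed=7))
        b = simulate_karyotypes(SimConfig(seed=7))
        for ga, gb in zip(a.species, b.species):
            pd.testing.assert_frame_equal(ga.to_ancestor.to_frame(), gb.to_ancestor.to_frame())
            pd.testing.assert_frame_equal(ga.to_reference.to_frame(), gb.to_reference.to_frame())
        assert a.truth.rearrangement_log == b.truth.rearrangement_log
        for pa, pb in zip(a.truth.planted, b.truth.planted):
            assert (pa.region_class, pa.anc_chrom, pa.start, pa.end) == (
                pb.region_class, pb.anc_chrom, pb.start, pb.end)
            assert pa.species_intervals == pb.species_intervals

    def test_blocks_tile_every_species_genome_exactly_once(self, scenario):
        for g in scenario.sim.species:
            by_chrom = {}
            for b in g.to_ancestor.blocks:
                by_chrom.setdefault(b.src_chrom, []).append((b.src_start, b.src_end))
            for chrom, ivs in by_chrom.items():
                ivs.sort()
                assert ivs[0][0] == 0 and ivs[-1][1] == g.chrom_sizes[chrom]
                assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))

    def test_direct_and_composed_ancestor_projection_agree(self, scenario):
        # species -> ancestor vs species -> reference -> ancestor on random points
        sim = scenario.sim
        ref_to_anc = sim.genome(sim.reference).to_ancestor
        rng = np.random.default_rng(0)
        for g in sim.species[1:]:
            chroms = list(g.chrom_sizes)
            for _ in range(250):
                chrom = chroms[rng.integers(len(chroms))]
                x = int(rng.integers(0, g.chrom_sizes[chrom] - 1))
                direct, _ = g.to_ancestor.project_region(chrom, x, x + 1, warn_unmapped=False)
                step1, _ = g.to_reference.project_region(chrom, x, x + 1, warn_unmapped=False)
                y = step1[0]
                composed, _ = ref_to_anc.project_region(
                    y["dst_chrom"], y["dst_start"], y["dst_start"] + 1, warn_unmapped=False
                )
                assert composed[0]["dst_chrom"] == direct[0]["dst_chrom"]
                assert abs(composed[0]["dst_start"] - direct[0]["dst_start"]) <= 1

    def test_planted_regions_survive_rearrangements_in_every_species(self, scenario):
        for p in scenario.sim.truth.planted:
            for g in scenario.sim.species:
                pieces = p.species_intervals[g.name]
                assert sum(e - s for _, s, e in pieces) == p.end - p.start

    def test_excess_fusions_rejected(self):
        with pytest.raises(ValueError, match="fusions"):
            SimConfig(n_fissions=0, n_fusions=10).validate()


class TestRecombinationLandscape:
    def test_degenerate_parameters_give_constant_rate(self):
        cfg = SimConfig(
            seed=0, telomere_boost=0.0, noise_sd=0.0, n_planted_cold=0, n_planted_hot=0,
            n_fissions=0, n_fusions=0, n_inversions=0,
        )
        sim = simulate_karyotypes(cfg)
        maps = simulate_recombination_landscape(sim)
        for m in maps.values():
            assert np.allclose(m.windows["rate"], cfg.base_rate)

    def test_planted_windows_rank_in_extreme_quartiles(self, scenario):
        sim = scenario.sim
        for g in sim.species:
            track = scenario.tracks[g.name]
            entries = track.entries.set_index(["chrom", "start"])
            for p in sim.truth.planted:
                want = "Q1" if p.region_class == "ALR" else "Q4"
                for chrom, start, end in p.species_intervals[g.name]:
                    inside = track.entries[
                        (track.entries["chrom"] == chrom)
                        & (track.entries["start"] >= start)
                        & (track.entries["end"] <= end)
                    ]
                    assert (inside["category"] == want).all()

    def test_planted_separation_without_noise(self):
        cfg = SimConfig(seed=3, noise_sd=0.0)
        sim = simulate_karyotypes(cfg)
        maps = simulate_recombination_landscape(sim)
        for g in sim.species:
            win = maps[g.name].windows
            cold, hot = [], []
            for p in sim.truth.planted:
                for chrom, start, end in p.species_intervals[g.name]:
                    sel = win[(win["chrom"] == chrom) & (win["start"] >= start) & (win["end"] <= end)]
                    (cold if p.region_class == "ALR" else hot).extend(sel["rate"])
            assert max(cold) < min(hot)

    def test_short_chromosome_windows_at_or_above_genome_median(self, scenario):
        for g in scenario.sim.species:
            win = scenario.maps[g.name].windows
            median = win["rate"].median()
            for chrom, length in g.chrom_sizes.items():
                if length < scenario.config.short_chrom_threshold:
                    planted = {
                        (c, s, e)
                        for p in scenario.sim.truth.planted
                        for (c, s, e) in p.species_intervals[g.name]
                    }
                    sub = win[win["chrom"] == chrom]
                    for row in sub.itertuples(index=False):
                        if any(c == chrom and row.start >= s and row.end <= e for c, s, e in planted):
                            continue
                        assert row.rate >= median * 0.999


class TestGenesAndPathways:
    def test_full_high_fraction_places_all_genes_in_hot_regions(self):
        cfg = SimConfig(seed=2, pathway_spec=(("PW", 20, 1.0),))
        sim = simulate_karyotypes(cfg)
        gs = simulate_genes_and_pathways(sim)
        pw = gs.ancestor_genes[gs.ancestor_genes["pathway"] == "PW"]
        assert len(pw) == 20 and (pw["planted_class"] == "AHR").all()

    def test_half_fraction_within_binomial_bounds(self):
        cfg = SimConfig(seed=2, pathway_spec=(("PW", 40, 0.5),))
        sim = simulate_karyotypes(cfg)
        hits = []
        for seed in range(30):
            gs = simulate_genes_and_pathways(sim, seed=seed)
            pw = gs.ancestor_genes[gs.ancestor_genes["pathway"] == "PW"]
            hits.append((pw["planted_class"] == "AHR").sum())
        mean = np.mean(hits)  # 99% band for mean of 30 binomial(40, .5) draws
        assert abs(mean - 20) < 2.6 * np.sqrt(40 * 0.25 / 30)

    def test_zero_loc_fraction_emits_no_loc_symbols(self):
        cfg = SimConfig(seed=2, loc_fraction=0.0)
        sim = simulate_karyotypes(cfg)
        gs = simulate_genes_and_pathways(sim)
        assert not gs.orthogroups["symbol"].str.startswith("LOC").any()

    def test_loc_symbols_resolvable_through_reference_anchor(self):
        cfg = SimConfig(seed=2, loc_fraction=0.3)
        sim = simulate_karyotypes(cfg)
        gs = simulate_genes_and_pathways(sim)
        mapping, unresolved = ar.resolve_loc_symbols(gs.orthogroups, anchor_species=(sim.reference,))
        assert unresolved == []
        assert mapping == gs.loc_map


class TestAlignmentPair:
    def test_equal_rates_give_matching_distance_matrices(self):
        a, b, _ = simulate_alignment_pair(TREE, 4000, rate_multiplier=1.0, seed=5)
        from ancrecomb.phylo import jc_distance_matrix

        da, db = jc_distance_matrix(a), jc_distance_matrix(b)
        assert np.allclose(da.data, db.data, atol=0.05)

    def test_no_missing_fraction_no_gaps(self):
        a, b, _ = simulate_alignment_pair(TREE, 500, missing_fraction=0.0, seed=5)
        assert "-" not in a.matrix and "-" not in b.matrix

    def test_missing_fraction_approximately_respected(self):
        a, _, _ = simulate_alignment_pair(TREE, 5000, missing_fraction=0.2, seed=5)
        assert abs((a.matrix == "-").mean() - 0.2) < 0.02

    def test_zero_columns_rejected(self):
        with pytest.raises(ValueError, match="n_columns"):
            simulate_alignment_pair(TREE, 0)

    def test_malformed_newick_rejected(self):
        with pytest.raises(Exception):
            simulate_alignment_pair("((t1:0.1,:;", 100)


class TestDeterminism:
    def test_identical_config_reproduces_identical_maps_and_genes(self):
        cfg = SimConfig(seed=9)
        out = []
        for _ in range(2):
            sim = simulate_karyotypes(cfg)
            maps = simulate_recombination_landscape(sim)
            gs = simulate_genes_and_pathways(sim)
            out.append((maps, gs))
        for sp in out[0][0]:
            pd.testing.assert_frame_equal(out[0][0][sp].windows, out[1][0][sp].windows)
        pd.testing.assert_frame_equal(out[0][1].orthogroups, out[1][1].orthogroups)
        assert out[0][1].pathways == out[1][1].pathways
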