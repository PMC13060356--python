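"""Synthetic multi-species data with planted ground truth.

Generates everything the downstream pipeline consumes: an ancestral
karyotype, per-species karyotypes derived from it by fission/fusion/
inversion (with full synteny bookkeeping), recombination landscapes shaped
like real mammalian maps — elevated toward the ends of long chromosomes,
depressed in their middles, uniformly elevated on short chromosomes — with
planted cold (ALR) and hot (AHR) regions shared across species through the
synteny, gene annotations and pathway sets with a controllable skew toward
the planted hot regions, and toy alignments evolved on a user tree at
contrasting substitution rates.

Planted regions are placed on the ancestor and propagated through the
rearrangements, so their cross-species conservation holds by construction.
Rearrangement breakpoints snap to a coordinate lattice (the analysis window
size by default) so that planted regions tile analysis windows cleanly, and
by default breakpoints avoid planted-region interiors; both behaviours are
configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import io as aio
from .phylo import Alignment
from .ratemaps import RecombinationMap
from .synteny import SyntenyBlock, SyntenyMap, identity_map

DEFAULT_ANCESTRAL_CHROMOSOMES = (
    ("ANC1", 63_000_000),
    ("ANC2", 49_500_000),
    ("ANC3", 39_000_000),
    ("ANC4", 28_500_000),
    ("ANC5", 12_000_000),
    ("ANC6", 7_500_000),
)

DEFAULT_PATHWAY_SPEC = (
    ("HM_HOT_SKEW", 30, 0.9),
    ("HM_COLD_SKEW", 30, 0.1),
    ("HM_BALANCED", 30, 0.5),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic multi-species scenario.

    Defaults describe a four-species, ~200 Mb genome with 15 planted cold
    and 15 planted hot regions of two analysis windows each.
    """

    seed: int = 0
    n_species: int = 4
    ancestral_chromosomes: tuple[tuple[str, int], ...] = DEFAULT_ANCESTRAL_CHROMOSOMES
    n_fissions: int = 2
    n_fusions: int = 1
    n_inversions: int = 2
    breakpoint_resolution: int = 1_500_000
    telomere_boost: float = 3.0
    decay_fraction: float = 0.1  # telomere-effect decay length, as a fraction of chromosome length
    base_rate: float = 1.0
    short_chrom_threshold: int = 15_000_000
    n_planted_cold: int = 15
    n_planted_hot: int = 15
    planted_region_length: int = 3_000_000
    planted_margin: int = 1  # windows kept free at each chromosome end
    noise_sd: float = 0.25  # log-scale sd of multiplicative rate noise
    tile_size: int = 100_000
    gene_count: int = 800
    gene_length: int = 10_000
    pathway_spec: tuple[tuple[str, int, float], ...] = DEFAULT_PATHWAY_SPEC
    loc_fraction: float = 0.15
    protect_planted: bool = True

    def validate(self) -> None:
        res = self.breakpoint_resolution
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        for name, length in self.ancestral_chromosomes:
            if length <= 0:
                raise ValueError(f"ancestral chromosome {name} has non-positive length")
            if length % res:
                raise ValueError(f"ancestral chromosome {name} length must be a multiple of breakpoint_resolution")
        if self.planted_region_length < 2 * res:
            raise ValueError("planted regions must span at least two analysis windows")
        if self.planted_region_length % res:
            raise ValueError("planted_region_length must be a multiple of breakpoint_resolution")
        if self.telomere_boost < 0 or self.base_rate <= 0 or self.noise_sd < 0:
            raise ValueError("rate parameters out of range")
        if not (0 <= self.loc_fraction < 1):
            raise ValueError("loc_fraction must lie in [0, 1)")
        for name, n_genes, frac in self.pathway_spec:
            if n_genes < 0 or not (0 <= frac <= 1):
                raise ValueError(f"invalid pathway spec for {name}")
        if self.gene_count < sum(n for _, n, _ in self.pathway_spec):
            raise ValueError("gene_count smaller than total pathway membership")
        n_chroms = len(self.ancestral_chromosomes)
        if self.n_fusions > n_chroms + self.n_fissions - 1:
            raise ValueError(
                f"{self.n_fusions} fusions impossible with {n_chroms} chromosomes and {self.n_fissions} fissions"
            )


@dataclass
class PlantedRegion:
    region_class: str  # 'ALR' (cold) or 'AHR' (hot)
    anc_chrom: str
    start: int
    end: int
    species_intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)


@dataclass
class GroundTruth:
    planted: list[PlantedRegion]
    rearrangement_log: list[dict]

    def by_class(self, region_class: str) -> list[PlantedRegion]:
        return [p for p in self.planted if p.region_class == region_class]


@dataclass
class SpeciesGenome:
    name: str
    chrom_sizes: dict[str, int]
    to_ancestor: SyntenyMap
    to_reference: SyntenyMap | None = None


@dataclass
class Simulation:
    config: SimConfig
    ancestor_sizes: dict[str, int]
    species: list[SpeciesGenome]
    truth: GroundTruth
    reference: str

    def genome(self, name: str) -> SpeciesGenome:
        return next(g for g in self.species if g.name == name)


# ---------------------------------------------------------------------------
# karyotype mechanics: a chromosome is an ordered list of ancestor segments

Segment = tuple[str, int, int, str]  # anc_chrom, anc_start, anc_end, strand


def _seg_len(segs: Sequence[Segment]) -> int:
    return sum(e - s for _, s, e, _ in segs)


def _split_segments(segs: Sequence[Segment], pos: int) -> tuple[list[Segment], list[Segment]]:
    """Split a segment list at species-coordinate ``pos``."""
    left: list[Segment] = []
    right: list[Segment] = []
    cursor = 0
    for seg in segs:
        c, s, e, strand = seg
        length = e - s
        if pos <= cursor:
            right.append(seg)
        elif pos >= cursor + length:
            left.append(seg)
        else:
            off = pos - cursor
            if strand == "+":
                left.append((c, s, s + off, "+"))
                right.append((c, s + off, e, "+"))
            else:  # species left end corresponds to ancestor right end
                left.append((c, e - off, e, "-"))
                right.append((c, s, e - off, "-"))
        cursor += length
    return left, right


def _reverse_segments(segs: Sequence[Segment]) -> list[Segment]:
    return [(c, s, e, "+" if strand == "-" else "-") for c, s, e, strand in reversed(segs)]


def _ancestor_coord_at(segs: Sequence[Segment], pos: int) -> tuple[str, int]:
    """Ancestor (chrom, coordinate) at species boundary position ``pos``."""
    cursor = 0
    for c, s, e, strand in segs:
        length = e - s
        if cursor <= pos <= cursor + length:
            off = pos - cursor
            return (c, s + off) if strand == "+" else (c, e - off)
        cursor += length
    raise ValueError(f"position {pos} beyond chromosome end {cursor}")


def apply_fission(chroms: list[list[Segment]], index: int, pos: int) -> None:
    segs = chroms.pop(index)
    if not 0 < pos < _seg_len(segs):
        raise ValueError(f"fission position {pos} not strictly inside the chromosome")
    left, right = _split_segments(segs, pos)
    chroms.insert(index, right)
    chroms.insert(index, left)


def apply_fusion(chroms: list[list[Segment]], i: int, j: int, flip_second: bool = False) -> None:
    if i == j:
        raise ValueError("fusion needs two distinct chromosomes")
    a = chroms[i]
    b = chroms[j]
    fused = a + (_reverse_segments(b) if flip_second else list(b))
    for k in sorted((i, j), reverse=True):
        chroms.pop(k)
    chroms.insert(min(i, j), fused)


def apply_inversion(chroms: list[list[Segment]], index: int, start: int, end: int) -> None:
    segs = chroms[index]
    if not 0 <= start < end <= _seg_len(segs):
        raise ValueError(f"invalid inversion interval [{start}, {end})")
    left, rest = _split_segments(segs, start)
    mid, right = _split_segments(rest, end - start)
    chroms[index] = left + _reverse_segments(mid) + right


def _planted_interiors(planted: Sequence[PlantedRegion]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for p in planted:
        out.setdefault(p.anc_chrom, []).append((p.start, p.end))
    return out


def _breakpoint_ok(
    segs: Sequence[Segment], pos: int, interiors: Mapping[str, list[tuple[int, int]]]
) -> bool:
    c, a = _ancestor_coord_at(segs, pos)
    return not any(s < a < e for s, e in interiors.get(c, []))


def _place_planted(config: SimConfig, rng: np.random.Generator) -> list[PlantedRegion]:
    """Place non-overlapping, non-adjacent planted regions on the ancestor.

    Regions go on long chromosomes only, at lattice positions, keeping
    ``planted_margin`` windows free at each chromosome end and at least one
    window between consecutive regions (so neighbouring planted regions can
    never merge into one call).
    """
    res = config.breakpoint_resolution
    w = config.planted_region_length // res
    margin = config.planted_margin
    n_total = config.n_planted_cold + config.n_planted_hot
    long_chroms = [
        (name, length)
        for name, length in config.ancestral_chromosomes
        if length >= config.short_chrom_threshold
    ]
    capacities = []
    for name, length in long_chroms:
        usable = length // res - 2 * margin
        capacities.append(max((usable + 1) // (w + 1), 0))
    if sum(capacities) < n_total:
        raise ValueError(
            f"cannot place {n_total} planted regions of {w} windows on the long chromosomes"
        )
    # spread regions over chromosomes proportionally to capacity, at random
    counts = [0] * len(long_chroms)
    order = rng.permutation(
        np.repeat(np.arange(len(long_chroms)), capacities)
    )
    for idx in order[:n_total]:
        counts[idx] += 1
    regions: list[tuple[str, int, int]] = []
    for (name, length), k in zip(long_chroms, counts):
        if k == 0:
            continue
        usable = length // res - 2 * margin
        slack = usable - (k * w + (k - 1))
        gaps = rng.multinomial(slack, np.ones(k + 1) / (k + 1))
        cursor = margin + int(gaps[0])
        for r in range(k):
            start = cursor * res
            regions.append((name, start, start + w * res))
            cursor += w + 1 + int(gaps[r + 1])
    labels = np.array(["ALR"] * config.n_planted_cold + ["AHR"] * config.n_planted_hot)
    rng.shuffle(labels)
    regions.sort()
    return [
        PlantedRegion(label, chrom, start, end)
        for (chrom, start, end), label in zip(regions, labels)
    ]


def simulate_karyotypes(config: SimConfig) -> Simulation:
    """Derive per-species karyotypes from the ancestor, with synteny and truth.

    Applies, per species, ``n_fissions`` fissions, then ``n_fusions``
    fusions, then ``n_inversions`` inversions, all at lattice breakpoints.
    Every species genome is tiled exactly once by its ancestor synteny
    blocks; species-to-reference maps are obtained by composing through the
    ancestor. The first species acts as the reference.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    planted = _place_planted(config, rng)
    interiors = _planted_interiors(planted) if config.protect_planted else {}
    res = config.breakpoint_resolution
    log: list[dict] = []
    genomes: list[SpeciesGenome] = []
    species_names = [f"sp{i + 1}" for i in range(config.n_species)]
    for sp in species_names:
        chroms: list[list[Segment]] = [
            [(name, 0, length, "+")] for name, length in config.ancestral_chromosomes
        ]
        for _ in range(config.n_fissions):
            candidates = []
            for ci, segs in enumerate(chroms):
                n_cells = _seg_len(segs) // res
                for k in range(1, n_cells):
                    if _breakpoint_ok(segs, k * res, interiors):
                        candidates.append((ci, k * res))
            if not candidates:
                raise ValueError(f"{sp}: no admissible fission breakpoint")
            ci, pos = candidates[rng.integers(len(candidates))]
            anc = _ancestor_coord_at(chroms[ci], pos)
            apply_fission(chroms, ci, pos)
            log.append({"species": sp, "op": "fission", "ancestor_breakpoint": anc})
        for _ in range(config.n_fusions):
            if len(chroms) < 2:
                raise ValueError(f"{sp}: not enough chromosomes left to fuse")
            i, j = rng.choice(len(chroms), size=2, replace=False)
            flip = bool(rng.integers(2))
            first = [c for c, *_ in chroms[i]]
            second = [c for c, *_ in chroms[j]]
            apply_fusion(chroms, int(i), int(j), flip)
            log.append({"species": sp, "op": "fusion", "joined": [first, second], "flipped": flip})
        for _ in range(config.n_inversions):
            candidates = []
            for ci, segs in enumerate(chroms):
                n_cells = _seg_len(segs) // res
                if n_cells < 2:
                    continue
                candidates.append(ci)
            if not candidates:
                raise ValueError(f"{sp}: no chromosome long enough to invert")
            for _attempt in range(200):
                ci = candidates[rng.integers(len(candidates))]
                n_cells = _seg_len(chroms[ci]) // res
                a, b = sorted(rng.choice(n_cells + 1, size=2, replace=False))
                if b == a:
                    continue
                start, end = int(a) * res, int(b) * res
                if _breakpoint_ok(chroms[ci], start, interiors) and _breakpoint_ok(
                    chroms[ci], end, interiors
                ):
                    anc_a = _ancestor_coord_at(chroms[ci], start)
                    anc_b = _ancestor_coord_at(chroms[ci], end)
                    apply_inversion(chroms, ci, start, end)
                    log.append(
                        {"species": sp, "op": "inversion", "ancestor_endpoints": [anc_a, anc_b]}
                    )
                    break
            else:
                raise ValueError(f"{sp}: failed to sample an admissible inversion")
        # name chromosomes longest-first and emit synteny blocks
        chroms.sort(key=_seg_len, reverse=True)
        sizes: dict[str, int] = {}
        blocks: list[SyntenyBlock] = []
        for ci, segs in enumerate(chroms):
            name = f"chr{ci + 1}"
            sizes[name] = _seg_len(segs)
            cursor = 0
            for c, s, e, strand in segs:
                blocks.append(SyntenyBlock(name, cursor, cursor + (e - s), c, s, e, strand))
                cursor += e - s
        genomes.append(SpeciesGenome(sp, sizes, SyntenyMap(blocks)))

    reference = genomes[0]
    anc_to_ref = reference.to_ancestor.invert()
    for g in genomes:
        if g.name == reference.name:
            g.to_reference = identity_map(g.chrom_sizes)
        else:
            g.to_reference = g.to_ancestor.compose(anc_to_ref)

    # propagate planted regions into every species
    for g in genomes:
        anc_to_sp = g.to_ancestor.invert()
        for p in planted:
            mapped, unmapped = anc_to_sp.project_region(p.anc_chrom, p.start, p.end, warn_unmapped=False)
            pieces = sorted((m["dst_chrom"], m["dst_start"], m["dst_end"]) for m in mapped)
            if len(pieces) > 1:
                # merge pieces that are contiguous on the species genome
                merged = [list(pieces[0])]
                for c, s, e in pieces[1:]:
                    if c == merged[-1][0] and s == merged[-1][2]:
                        merged[-1][2] = e
                    else:
                        merged.append([c, s, e])
                pieces = [tuple(m) for m in merged]
            if len(pieces) > 1:
                warnings.warn(
                    f"planted region {p.anc_chrom}:{p.start}-{p.end} split by a rearrangement in {g.name}"
                )
            if unmapped:
                raise AssertionError("planted region lost during rearrangement bookkeeping")
            p.species_intervals[g.name] = pieces

    truth = GroundTruth(planted, log)
    anc_sizes = {name: length for name, length in config.ancestral_chromosomes}
    return Simulation(config, anc_sizes, genomes, truth, reference.name)


# ---------------------------------------------------------------------------
# recombination landscapes


def _base_curve(position: np.ndarray, length: int, config: SimConfig) -> np.ndarray:
    if length < config.short_chrom_threshold:
        return np.full_like(position, config.base_rate * (1 + config.telomere_boost), dtype=float)
    decay = config.decay_fraction * length
    dist = np.minimum(position, length - position)
    return config.base_rate * (1 + config.telomere_boost * np.exp(-dist / decay))


def simulate_recombination_landscape(
    sim: Simulation, noise_sd: float | None = None
) -> dict[str, RecombinationMap]:
    """Per-species rate tracks with the planted regions written in.

    Background: a U-shaped telomere-boosted curve on long chromosomes,
    uniformly elevated short chromosomes, times log-normal noise. Planted
    cold regions are overwritten with draws from below the background's 10th
    percentile, planted hot regions with draws around and above its maximum
    (within the top decile), so planted windows rank in Q1/Q4 with high
    probability regardless of where rearrangements moved them.
    """
    config = sim.config
    sd = config.noise_sd if noise_sd is None else noise_sd
    out: dict[str, RecombinationMap] = {}
    for k, genome in enumerate(sim.species):
        rng = np.random.default_rng([config.seed, 2, k])
        frames = []
        for chrom, length in genome.chrom_sizes.items():
            starts = np.arange(0, length, config.tile_size)
            ends = np.minimum(starts + config.tile_size, length)
            mid = (starts + ends) / 2
            rate = _base_curve(mid, length, config)
            if sd > 0:
                rate = rate * np.exp(rng.normal(0.0, sd, size=len(rate)))
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "rate": rate}))
        track = pd.concat(frames, ignore_index=True)
        background = track["rate"].to_numpy()
        q10, q90 = np.quantile(background, [0.10, 0.90])
        top_span = max(float(background.max() - q90), 0.1 * max(q90, config.base_rate))
        for p in sim.truth.planted:
            for chrom, start, end in p.species_intervals[genome.name]:
                sel = (track["chrom"] == chrom) & (track["start"] >= start) & (track["end"] <= end)
                n = int(sel.sum())
                if p.region_class == "ALR":
                    track.loc[sel, "rate"] = q10 * rng.uniform(0.1, 0.7, size=n)
                else:
                    track.loc[sel, "rate"] = q90 + top_span * rng.uniform(0.7, 1.3, size=n)
        out[genome.name] = RecombinationMap(
            genome.name, track, provenance=f"synthetic(seed={config.seed},species={genome.name})"
        )
    return out


# ---------------------------------------------------------------------------
# genes and pathways


@dataclass
class GeneSim:
    ancestor_genes: pd.DataFrame  # symbol, chrom, start, end, pathway, planted_class
    species_genes: dict[str, pd.DataFrame]  # species -> symbol, chrom, start, end
    orthogroups: pd.DataFrame  # orthogroup, species, symbol
    pathways: dict[str, list[str]]
    loc_map: dict[str, str]  # species symbol (LOC...) -> canonical symbol


def _complement(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    cursor = 0
    for s, e in sorted(intervals):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return out


def _uniform_position(
    intervals: list[tuple[str, int, int]], gene_length: int, rng: np.random.Generator
) -> tuple[str, int, int]:
    usable = [(c, s, e) for c, s, e in intervals if e - s >= gene_length]
    if not usable:
        raise ValueError("no interval can hold a gene of the requested length")
    weights = np.array([e - s - gene_length + 1 for _, s, e in usable], dtype=float)
    idx = rng.choice(len(usable), p=weights / weights.sum())
    c, s, e = usable[idx]
    start = int(s + rng.integers(0, e - s - gene_length + 1))
    return c, start, start + gene_length


def simulate_genes_and_pathways(sim: Simulation, seed: int | None = None) -> GeneSim:
    """Place one-to-one orthologous genes and pathway files with planted skew.

    Each gene of a pathway with ``planted_high_fraction`` f lands inside a
    planted hot (AHR) region with probability f and uniformly elsewhere
    otherwise; genes outside any pathway are placed uniformly across the
    ancestor. Gene coordinates are propagated to every species through the
    synteny; a ``loc_fraction`` of non-reference symbols are replaced by LOC
    placeholders (resolvable through the orthogroup table).
    """
    config = sim.config
    rng = np.random.default_rng([config.seed if seed is None else seed, 3])
    hot = [(p.anc_chrom, p.start, p.end) for p in sim.truth.by_class("AHR")]
    cold = [(p.anc_chrom, p.start, p.end) for p in sim.truth.by_class("ALR")]
    genome = [(c, 0, length) for c, length in sim.ancestor_sizes.items()]
    hot_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in hot:
        hot_by_chrom.setdefault(c, []).append((s, e))
    non_hot = [
        (c, s, e)
        for c, length in sim.ancestor_sizes.items()
        for s, e in _complement(hot_by_chrom.get(c, []), length)
    ]
    if any(frac > 0 and n > 0 for _, n, frac in config.pathway_spec) and not hot:
        raise ValueError("pathway_spec requests planted-hot genes but no hot region was planted")

    rows = []
    pathways: dict[str, list[str]] = {}
    counter = 0
    for name, n_genes, frac in config.pathway_spec:
        members = []
        for _ in range(n_genes):
            counter += 1
            symbol = f"GENE{counter:04d}"
            members.append(symbol)
            if rng.random() < frac:
                c, s, e = _uniform_position(hot, config.gene_length, rng)
            else:
                c, s, e = _uniform_position(non_hot, config.gene_length, rng)
            rows.append((symbol, c, s, e, name))
        pathways[name] = members
    for _ in range(config.gene_count - counter):
        counter += 1
        symbol = f"GENE{counter:04d}"
        c, s, e = _uniform_position(genome, config.gene_length, rng)
        rows.append((symbol, c, s, e, None))
    genes = pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "pathway"])

    def planted_class(row) -> object:
        for c, s, e in hot:
            if row.chrom == c and row.start >= s and row.end <= e:
                return "AHR"
        for c, s, e in cold:
            if row.chrom == c and row.start >= s and row.end <= e:
                return "ALR"
        return None

    genes["planted_class"] = [planted_class(r) for r in genes.itertuples(index=False)]

    species_genes: dict[str, pd.DataFrame] = {}
    ortho_rows = []
    loc_map: dict[str, str] = {}
    loc_counter = 0
    for g in sim.species:
        anc_to_sp = g.to_ancestor.invert()
        sp_rows = []
        for row in genes.itertuples(index=False):
            mapped, _ = anc_to_sp.project_region(row.chrom, row.start, row.end, warn_unmapped=False)
            if not mapped:
                continue
            best = max(mapped, key=lambda m: m["dst_end"] - m["dst_start"])
            symbol = row.symbol
            if g.name != sim.reference and rng.random() < config.loc_fraction:
                loc_counter += 1
                symbol = f"LOC{100000 + loc_counter}"
                loc_map[symbol] = row.symbol
            sp_rows.append((symbol, best["dst_chrom"], best["dst_start"], best["dst_end"]))
            ortho_rows.append((f"OG{row.symbol[4:]}", g.name, symbol))
        species_genes[g.name] = pd.DataFrame(sp_rows, columns=["symbol", "chrom", "start", "end"])
    orthogroups = pd.DataFrame(ortho_rows, columns=["orthogroup", "species", "symbol"])
    return GeneSim(genes, species_genes, orthogroups, pathways, loc_map)


# ---------------------------------------------------------------------------
# toy alignments


def simulate_alignment_pair(
    tree: str | dendropy.Tree,
    n_columns: int,
    rate_multiplier: float = 1.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[Alignment, Alignment, dendropy.Tree]:
    """Evolve two alignments on one tree, the second at a scaled rate.

    Sites evolve independently under an equal-rates four-state substitution
    process (Jukes–Cantor); dataset B uses every branch length multiplied by
    ``rate_multiplier``. Missing symbols ('-') are injected per cell with
    probability ``missing_fraction``.
    """
    if n_columns <= 0:
        raise ValueError("n_columns must be positive")
    if rate_multiplier <= 0:
        raise ValueError("rate_multiplier must be positive")
    if not (0 <= missing_fraction < 1):
        raise ValueError("missing_fraction must lie in [0, 1)")
    t = tree if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng([seed, 4])
    alphabet = np.array(list("ACGT"))

    def evolve(mult: float) -> Alignment:
        states: dict[int, np.ndarray] = {}
        taxa: list[str] = []
        rows: list[np.ndarray] = []
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                states[id(node)] = rng.integers(4, size=n_columns)
            else:
                b = float(node.edge.length or 0.0) * mult
                p_same = 0.25 + 0.75 * np.exp(-4.0 * b / 3.0)
                parent = states[id(node.parent_node)]
                child = parent.copy()
                change = rng.random(n_columns) >= p_same
                child[change] = (parent[change] + rng.integers(1, 4, size=int(change.sum()))) % 4
                states[id(node)] = child
            if node.is_leaf():
                taxa.append(node.taxon.label)
                rows.append(states[id(node)])
        matrix = alphabet[np.vstack(rows)]
        if missing_fraction > 0:
            mask = rng.random(matrix.shape) < missing_fraction
            matrix = np.where(mask, "-", matrix)
        return Alignment(taxa, matrix)

    return evolve(1.0), evolve(rate_multiplier), t


# ---------------------------------------------------------------------------
# writers


def write_simulation(
    sim: Simulation,
    maps: Mapping[str, RecombinationMap],
    genes: GeneSim | None,
    out_dir: str,
) -> None:
    """Write the synthetic dataset as plain-text standard formats."""
    aio.ensure_dir(out_dir)
    aio.write_chrom_sizes(sim.ancestor_sizes, f"{out_dir}/ancestor.chrom.sizes")
    truth = {
        "reference": sim.reference,
        "planted": [
            {
                "class": p.region_class,
                "ancestor": [p.anc_chrom, p.start, p.end],
                "species": {sp: [list(t) for t in iv] for sp, iv in p.species_intervals.items()},
            }
            for p in sim.truth.planted
        ],
        "rearrangements": sim.truth.rearrangement_log,
    }
    with open(f"{out_dir}/ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    for g in sim.species:
        aio.write_chrom_sizes(g.chrom_sizes, f"{out_dir}/{g.name}.chrom.sizes")
        aio.write_synteny(g.to_ancestor.to_frame(), f"{out_dir}/{g.name}.to_ancestor.synteny.tsv")
        if g.to_reference is not None:
            aio.write_synteny(g.to_reference.to_frame(), f"{out_dir}/{g.name}.to_reference.synteny.tsv")
        if g.name in maps:
            aio.write_bedgraph(
                maps[g.name].windows, f"{out_dir}/{g.name}.rate.bedgraph", value_col="rate"
            )
    if genes is not None:
        for sp, table in genes.species_genes.items():
            aio.write_gff3_genes(table, f"{out_dir}/{sp}.genes.gff3")
        genes.orthogroups.to_csv(f"{out_dir}/orthogroups.tsv", sep="\t", index=False)
        aio.write_gmt(genes.pathways, f"{out_dir}/pathways.gmt")
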