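"""Gene-level analysis of conserved recombination regions.

Covers four steps: resolving placeholder LOC gene symbols through orthogroup
membership, assigning each gene to a recombination-rate quartile from its
species' window track (random tie-breaking when a gene straddles a category
boundary), building the set of one-to-one genes shared by all species, and
summarising how many genes of each conserved class (ALR/AHR) each species
retains in low/high-recombining territory.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalIndex
from .ratemaps import QuartileTrack

LOC_PATTERN = re.compile(r"^LOC\d+$")

DEFAULT_ANCHORS = ("human", "dog", "mouse")
RETAINED_LOW = frozenset({"Q1", "Q2"})
RETAINED_HIGH = frozenset({"Q3", "Q4"})
STRICT_LOW = frozenset({"Q1"})
STRICT_HIGH = frozenset({"Q4"})


@dataclass
class RetentionSummary:
    """Per-species retention of ALR/AHR gene sets plus all-species intersections."""

    table: pd.DataFrame  # species, region_class, retained, total, percent
    intersections: dict[str, set[str]]  # region_class -> genes extreme in all species
    retained_sets: dict[str, frozenset[str]]
    strict_sets: dict[str, frozenset[str]]


def resolve_loc_symbols(
    orthogroups: pd.DataFrame,
    anchor_species: Sequence[str] = DEFAULT_ANCHORS,
) -> tuple[dict[str, str], list[str]]:
    """Resolve LOC placeholder symbols to named orthologs.

    ``orthogroups`` is a long table (orthogroup, species, symbol). A LOC
    symbol takes the name of a non-LOC ortholog in its orthogroup when that
    name occurs in an anchor species or in at least two species; conflicting
    candidate names, or a LOC appearing in more than one orthogroup, leave it
    unresolved. Returns (mapping LOC->name, unresolved LOC list).
    """
    required = {"orthogroup", "species", "symbol"}
    if not required <= set(orthogroups.columns):
        raise ValueError(f"orthogroup table needs columns {sorted(required)}")
    anchor_set = set(anchor_species)
    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    loc_groups = (
        orthogroups[orthogroups["symbol"].str.match(LOC_PATTERN)]
        .groupby("symbol")["orthogroup"]
        .nunique()
    )
    multi = set(loc_groups[loc_groups > 1].index)
    for og, sub in orthogroups.groupby("orthogroup", sort=True):
        named = sub[~sub["symbol"].str.match(LOC_PATTERN)]
        locs = sub[sub["symbol"].str.match(LOC_PATTERN)]
        if locs.empty:
            continue
        candidates = sorted(named["symbol"].unique())
        for loc in sorted(locs["symbol"].unique()):
            if loc in multi:
                unresolved.append(loc)
                continue
            if len(candidates) != 1:
                unresolved.append(loc)
                continue
            name = candidates[0]
            carriers = set(named.loc[named["symbol"] == name, "species"])
            if carriers & anchor_set or len(carriers) >= 2:
                mapping[loc] = name
            else:
                unresolved.append(loc)
    return mapping, sorted(set(unresolved))


def apply_symbol_resolution(genes: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    out = genes.copy()
    out["symbol"] = out["symbol"].map(lambda s: mapping.get(s, s))
    return out


def assign_gene_categories(
    genes: pd.DataFrame,
    track: QuartileTrack,
    seed: int,
) -> pd.Series:
    """Assign each gene (chrom, start, end rows) a quartile category.

    The category is taken from the categorised windows the gene overlaps:
    a single category propagates directly; otherwise the category covering
    the most overlapped windows wins, and ties — the typical case being a
    gene straddling one category boundary — are resolved by a seeded uniform
    draw among the tied categories. Genes overlapping no categorised window
    are unassigned (NA).
    """
    rng = np.random.default_rng(seed)
    index = IntervalIndex(track.entries)
    cats = index.df["category"]
    out = []
    for row in genes.itertuples(index=False):
        rows = index.query(row.chrom, row.start, row.end)
        overlapped = cats.loc[rows]
        counts: dict[str, int] = {}
        for c in overlapped:
            if not pd.isna(c):
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append(pd.NA)
            continue
        best = max(counts.values())
        tied = sorted(c for c, n in counts.items() if n == best)
        out.append(tied[0] if len(tied) == 1 else tied[rng.integers(len(tied))])
    return pd.Series(out, index=genes.index, dtype="string")


def shared_gene_set(per_species_genes: Mapping[str, pd.DataFrame]) -> tuple[set[str], list[str]]:
    """Symbols categorised exactly once in every species.

    Duplicated symbols within a species break the one-to-one assumption and
    are excluded (returned in the log). Warns when the intersection is empty.
    """
    if len(per_species_genes) < 2:
        raise ValueError("shared gene set needs at least two species")
    shared: set[str] | None = None
    log: list[str] = []
    for sp, genes in per_species_genes.items():
        cat = genes[genes["category"].notna()] if "category" in genes else genes
        counts = cat["symbol"].value_counts()
        dups = set(counts[counts > 1].index)
        if dups:
            log.append(f"{sp}: excluded {len(dups)} duplicated symbol(s)")
        ok = set(counts[counts == 1].index)
        shared = ok if shared is None else shared & ok
    assert shared is not None
    if not shared:
        warnings.warn("shared gene set across species is empty")
    return shared, log


def retention_summary(
    class_genes: Mapping[str, Iterable[str]],
    per_species_categories: Mapping[str, Mapping[str, str]],
    retained_low: frozenset[str] = RETAINED_LOW,
    retained_high: frozenset[str] = RETAINED_HIGH,
    strict_low: frozenset[str] = STRICT_LOW,
    strict_high: frozenset[str] = STRICT_HIGH,
) -> RetentionSummary:
    """Count, per species, how many ALR/AHR genes stay in matching territory.

    ``class_genes`` maps 'ALR'/'AHR' to the reference-derived gene symbols of
    that class; ``per_species_categories`` maps species -> {symbol: quartile}.
    A gene is *retained* when its category falls in the class's retained set
    ({Q1, Q2} for ALR, {Q3, Q4} for AHR by default). The all-species
    intersection uses the strict single-extreme sets (Q1 / Q4) — both set
    definitions are parameters and echoed in the result.
    """
    retained_sets = {"ALR": frozenset(retained_low), "AHR": frozenset(retained_high)}
    strict_sets = {"ALR": frozenset(strict_low), "AHR": frozenset(strict_high)}
    rows = []
    intersections: dict[str, set[str]] = {}
    for cls, symbols in class_genes.items():
        symbols = sorted(set(symbols))
        if not symbols:
            raise ValueError(f"empty gene set for class {cls}")
        for sp, categories in per_species_categories.items():
            retained = sum(1 for g in symbols if categories.get(g) in retained_sets[cls])
            rows.append((sp, cls, retained, len(symbols), 100.0 * retained / len(symbols)))
        intersections[cls] = {
            g
            for g in symbols
            if all(categories.get(g) in strict_sets[cls] for categories in per_species_categories.values())
        }
    table = pd.DataFrame(rows, columns=["species", "region_class", "retained", "total", "percent"])
    return RetentionSummary(table, intersections, retained_sets, strict_sets)


def genes_in_calls(
    genes: pd.DataFrame,
    alr_calls: Sequence,
    ahr_calls: Sequence,
) -> dict[str, set[str]]:
    """Partition reference-species genes into ALR/AHR sets by call overlap.

    A gene joins the class whose calls it overlaps most (in bp); genes
    overlapping neither class are left out.
    """
    out: dict[str, set[str]] = {"ALR": set(), "AHR": set()}
    tables = {}
    for cls, calls in (("ALR", alr_calls), ("AHR", ahr_calls)):
        df = pd.DataFrame(
            [(c.chrom, c.start, c.end) for c in calls], columns=["chrom", "start", "end"]
        )
        tables[cls] = IntervalIndex(df) if len(df) else None
    for row in genes.itertuples(index=False):
        best_cls, best_bp = None, 0
        for cls, idx in tables.items():
            if idx is None:
                continue
            bp = 0
            for r in idx.query(row.chrom, row.start, row.end):
                bp += min(idx.df.at[r, "end"], row.end) - max(idx.df.at[r, "start"], row.start)
            if bp > best_bp:
                best_cls, best_bp = cls, bp
        if best_cls:
            out[best_cls].add(row.symbol)
    return out
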