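"""Cross-species consensus calling of conserved recombination regions.

Given per-species quartile tracks and synteny between a chosen reference and
every other species, this module identifies ancestrally low-recombining
(ALR) and ancestrally high-recombining (AHR) regions: reference intervals
where at least ``min_support`` of the species (3 of 4 by default) carry the
same rate class. A collinear region classifies as *low* when its windows
come from the two lowest quartiles {Q1, Q2}, *high* for {Q3, Q4}; a region
mixing both sides takes the side covering at least half of its windows, with
an exact tie left uncalled. Same-class calls within 1 Mb are merged, and any
residual ALR/AHR overlap is cut at the midpoint of the overlapped interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalIndex
from .ratemaps import QuartileTrack
from .synteny import SyntenyMap

LOW_SET = frozenset({"Q1", "Q2"})
HIGH_SET = frozenset({"Q3", "Q4"})
CLASS_OF_SIDE = {"low": "ALR", "high": "AHR"}
EXTREME_OF_SIDE = {"low": "Q1", "high": "Q4"}


@dataclass
class ConservedCall:
    """An ALR or AHR interval on the reference genome."""

    region_class: str  # 'ALR' | 'AHR'
    chrom: str
    start: int
    end: int
    support: int
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.region_class not in ("ALR", "AHR"):
            raise ValueError(f"class must be ALR or AHR, got {self.region_class!r}")
        if self.end <= self.start:
            raise ValueError(f"degenerate call {self.chrom}:{self.start}-{self.end}")

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def classify_region(
    categories: Sequence[str | None],
    low_set: frozenset[str] = LOW_SET,
    high_set: frozenset[str] = HIGH_SET,
) -> str:
    """Classify one species' window categories within a collinear region.

    Returns 'low', 'high', or 'none'. Uncategorised (None/NA) windows are
    ignored; a region whose windows split exactly 50/50 between the low and
    high sides is ambiguous and returns 'none', as does a region with no
    categorised window at all.
    """
    cats = [c for c in categories if c is not None and not pd.isna(c)]
    if not cats:
        return "none"
    unknown = set(cats) - (low_set | high_set)
    if unknown:
        raise ValueError(f"unknown rate categories {sorted(unknown)}")
    n_low = sum(c in low_set for c in cats)
    n_high = len(cats) - n_low
    if n_low > n_high:
        return "low"
    if n_high > n_low:
        return "high"
    return "none"


def consensus_call(
    per_species_classes: Mapping[str, str],
    region: tuple[str, int, int],
    min_support: int = 3,
    n_species: int = 4,
) -> ConservedCall | None:
    """Emit a conserved call when enough species agree on a non-'none' class."""
    if n_species < min_support:
        raise ValueError(f"n_species ({n_species}) < min_support ({min_support})")
    if len(per_species_classes) < n_species:
        raise ValueError(
            f"need classifications for {n_species} species, got {len(per_species_classes)}"
        )
    counts = {"low": 0, "high": 0}
    for cls in per_species_classes.values():
        if cls in counts:
            counts[cls] += 1
    side = max(counts, key=lambda s: counts[s])
    if counts["low"] == counts["high"]:
        return None
    if counts[side] < min_support:
        return None
    chrom, start, end = region
    return ConservedCall(CLASS_OF_SIDE[side], chrom, start, end, counts[side], (f"{chrom}:{start}-{end}",))


def merge_calls(calls: Sequence[ConservedCall], max_gap: int = 1_000_000) -> list[ConservedCall]:
    """Merge same-class calls on one chromosome separated by <= max_gap bp.

    Support of a merged call is the maximum of its constituents. Idempotent.
    """
    if not calls:
        return []
    classes = {c.region_class for c in calls}
    if len(classes) > 1:
        raise ValueError(f"merge_calls expects a single class, got {sorted(classes)}")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    merged = [replace(ordered[0])]
    for call in ordered[1:]:
        last = merged[-1]
        if call.chrom == last.chrom and call.start - last.end <= max_gap:
            merged[-1] = replace(
                last,
                end=max(last.end, call.end),
                support=max(last.support, call.support),
                provenance=last.provenance + call.provenance,
            )
        else:
            merged.append(replace(call))
    return merged


def resolve_overlaps(
    alr_calls: Sequence[ConservedCall], ahr_calls: Sequence[ConservedCall]
) -> tuple[list[ConservedCall], list[ConservedCall], list[str]]:
    """Make the ALR and AHR call sets mutually disjoint.

    A partial overlap is cut at the integer midpoint of the overlapped
    interval, each class keeping its own side. A call fully contained in a
    call of the other class is dropped (the containing call wins); when the
    two calls are identical the AHR call is dropped — an arbitrary but
    deterministic tie-break. Returns (alr, ahr, event log).
    """
    alr = sorted((replace(c) for c in alr_calls), key=lambda c: (c.chrom, c.start))
    ahr = sorted((replace(c) for c in ahr_calls), key=lambda c: (c.chrom, c.start))
    events: list[str] = []
    keep_alr = [True] * len(alr)
    keep_ahr = [True] * len(ahr)
    for i, a in enumerate(alr):
        for j, h in enumerate(ahr):
            if not keep_alr[i] or not keep_ahr[j] or a.chrom != h.chrom:
                continue
            o1, o2 = max(a.start, h.start), min(a.end, h.end)
            if o2 <= o1:
                continue
            a_in_h = a.start >= h.start and a.end <= h.end
            h_in_a = h.start >= a.start and h.end <= a.end
            if h_in_a:  # identical intervals also land here: AHR dropped
                keep_ahr[j] = False
                events.append(f"dropped contained AHR {h.chrom}:{h.start}-{h.end} inside ALR {a.start}-{a.end}")
                continue
            if a_in_h:
                keep_alr[i] = False
                events.append(f"dropped contained ALR {a.chrom}:{a.start}-{a.end} inside AHR {h.start}-{h.end}")
                continue
            mid = (o1 + o2) // 2
            if a.start < h.start:
                alr[i] = a = replace(a, end=mid)
                ahr[j] = h = replace(h, start=mid)
            else:
                alr[i] = a = replace(a, start=mid)
                ahr[j] = h = replace(h, end=mid)
            events.append(f"cut ALR/AHR overlap on {a.chrom} at midpoint {mid}")
    return (
        [c for c, k in zip(alr, keep_alr) if k],
        [c for c, k in zip(ahr, keep_ahr) if k],
        events,
    )


def _extreme_runs(track: QuartileTrack, extreme: str, min_run: int) -> list[tuple[str, int, int, int]]:
    """Maximal runs of coordinate-adjacent windows in the extreme category.

    Returns (chrom, start, end, n_windows) for runs of at least ``min_run``
    windows.
    """
    runs = []
    for chrom, sub in track.entries.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur: list[tuple[int, int]] = []
        for row in sub.itertuples(index=False):
            hit = (not pd.isna(row.category)) and row.category == extreme
            adjacent = bool(cur) and row.start == cur[-1][1]
            if hit and (not cur or adjacent):
                cur.append((row.start, row.end))
            else:
                if len(cur) >= min_run:
                    runs.append((chrom, cur[0][0], cur[-1][1], len(cur)))
                cur = [(row.start, row.end)] if hit else []
        if len(cur) >= min_run:
            runs.append((chrom, cur[0][0], cur[-1][1], len(cur)))
    return runs


def _categories_in_region(
    track_index: IntervalIndex,
    categories: np.ndarray,
    pieces: Sequence[tuple[str, int, int]],
    min_window_overlap: int,
) -> list[str | None]:
    cats: list[str | None] = []
    for chrom, start, end in pieces:
        for row in track_index.query(chrom, start, end):
            wstart = track_index.df.at[row, "start"]
            wend = track_index.df.at[row, "end"]
            if min(wend, end) - max(wstart, start) < min_window_overlap:
                continue  # sub-resolution sliver from projection rounding
            cats.append(categories[row])
    return cats


def call_conserved_regions(
    tracks: Mapping[str, QuartileTrack],
    reference: str,
    ref_to_species: Mapping[str, SyntenyMap],
    min_support: int = 3,
    n_species: int | None = None,
    min_run: int = 2,
    max_gap: int = 1_000_000,
    min_window_overlap: int = 1_000,
) -> tuple[list[ConservedCall], list[ConservedCall], list[str]]:
    """Call ALR/AHR regions from per-species quartile tracks.

    Candidate regions are maximal runs of at least ``min_run`` consecutive
    reference windows in an extreme quartile (Q1 for low, Q4 for high). Each
    candidate is lifted through synteny to every other species, the lifted
    windows are classified with the two-quartile mixture rule, and a call is
    emitted when >= ``min_support`` species (the reference included) agree.
    Calls are then merged per class and ALR/AHR overlaps resolved.

    ``ref_to_species`` maps each non-reference species name to a
    reference->species synteny map; a species absent from a region's synteny
    counts as 'none' there. Returns (alr_calls, ahr_calls, log).
    """
    if reference not in tracks:
        raise ValueError(f"reference species {reference!r} has no quartile track")
    species = sorted(tracks)
    if n_species is None:
        n_species = len(species)
    if len(species) < n_species:
        raise ValueError(f"need {n_species} species tracks, have {len(species)}")
    indexes = {sp: IntervalIndex(tracks[sp].entries) for sp in species}
    cats = {sp: indexes[sp].df["category"].to_numpy(dtype=object) for sp in species}
    log: list[str] = []
    calls: dict[str, list[ConservedCall]] = {"ALR": [], "AHR": []}
    for side in ("low", "high"):
        extreme = EXTREME_OF_SIDE[side]
        for chrom, start, end, n_win in _extreme_runs(tracks[reference], extreme, min_run):
            per_species: dict[str, str] = {}
            for sp in species:
                if sp == reference:
                    pieces: list[tuple[str, int, int]] = [(chrom, start, end)]
                else:
                    smap = ref_to_species.get(sp)
                    if smap is None:
                        per_species[sp] = "none"
                        log.append(f"{sp}: no synteny map; counted as none at {chrom}:{start}-{end}")
                        continue
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mapped, unmapped = smap.project_region(chrom, start, end)
                    if unmapped:
                        log.append(
                            f"{sp}: {len(unmapped)} unmapped sub-interval(s) lifting {chrom}:{start}-{end}"
                        )
                    pieces = [(m["dst_chrom"], m["dst_start"], m["dst_end"]) for m in mapped]
                window_cats = _categories_in_region(indexes[sp], cats[sp], pieces, min_window_overlap)
                per_species[sp] = classify_region(window_cats)
            call = consensus_call(per_species, (chrom, start, end), min_support, n_species)
            if call is not None and call.region_class == CLASS_OF_SIDE[side]:
                calls[call.region_class].append(call)
            else:
                log.append(f"no consensus for {side} candidate {chrom}:{start}-{end} ({per_species})")
    alr = merge_calls(calls["ALR"], max_gap) if calls["ALR"] else []
    ahr = merge_calls(calls["AHR"], max_gap) if calls["AHR"] else []
    alr, ahr, events = resolve_overlaps(alr, ahr)
    log.extend(events)
    return alr, ahr, log


def calls_to_frame(calls: Sequence[ConservedCall]) -> pd.DataFrame:
    """BED6-style table: name = class:support, score = support."""
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.end, f"{c.region_class}:{c.support}", c.support, ".")
            for c in sorted(calls, key=lambda c: (c.chrom, c.start))
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
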