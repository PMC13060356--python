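"""Syntenic fragments and coordinate projection between karyotypes.

A syntenic fragment (SF) links an interval on a source genome to a collinear
interval on a destination genome (an extant reference or a reconstructed
ancestral karyotype) with an orientation. Coordinates are projected across a
fragment by linear interpolation:

    mapped = dst_start + (attr - src_start) / (src_end - src_start) * (dst_end - dst_start)

for a co-oriented ('+') fragment; an inverted ('-') fragment measures the
scaled offset from ``dst_end`` instead. Results are rounded to the nearest
integer base pair (half up) and always fall inside the destination fragment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SYNTENY_COLUMNS


@dataclass(frozen=True)
class SyntenyBlock:
    """One collinear fragment pair; all coordinates 0-based half-open."""

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    dst_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.src_end <= self.src_start or self.dst_end <= self.dst_start:
            raise ValueError(f"degenerate synteny block {self}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def src_length(self) -> int:
        return self.src_end - self.src_start

    @property
    def dst_length(self) -> int:
        return self.dst_end - self.dst_start


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def project_coordinate(block: SyntenyBlock, attribute: int) -> int:
    """Project one source coordinate through a syntenic fragment.

    ``attribute`` (a start or end coordinate of a region of interest) must
    lie within [src_start, src_end]. The projection interpolates linearly
    between the fragment's destination bounds, reading right-to-left for
    inverted fragments, and is clamped to the destination fragment after
    rounding.
    """
    if not (block.src_start <= attribute <= block.src_end):
        raise ValueError(
            f"coordinate {attribute} outside fragment bounds [{block.src_start}, {block.src_end}]"
        )
    offset = (attribute - block.src_start) / block.src_length * block.dst_length
    if block.strand == "+":
        mapped = _round_half_up(block.dst_start + offset)
    else:
        mapped = _round_half_up(block.dst_end - offset)
    return min(max(mapped, block.dst_start), block.dst_end)


class SyntenyMap:
    """A set of syntenic fragments from one genome to another.

    Fragments must not overlap on the source genome; gaps are permitted and
    reported by :meth:`project_region` rather than silently dropped.
    """

    def __init__(self, blocks: Iterable[SyntenyBlock]):
        self.blocks = sorted(blocks, key=lambda b: (b.src_chrom, b.src_start, b.src_end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[SyntenyBlock]]] = {}
        for b in self.blocks:
            self._by_chrom.setdefault(b.src_chrom, (None, None, []))[2].append(b)
        for chrom, (_, _, blist) in list(self._by_chrom.items()):
            starts = np.array([b.src_start for b in blist])
            ends = np.array([b.src_end for b in blist])
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"synteny fragments overlap on source chromosome {chrom}")
            self._by_chrom[chrom] = (starts, ends, blist)

    # ---- construction -------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SyntenyMap":
        return cls(
            SyntenyBlock(
                str(r.src_chrom), int(r.src_start), int(r.src_end),
                str(r.dst_chrom), int(r.dst_start), int(r.dst_end), str(r.strand),
            )
            for r in df.itertuples(index=False)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (b.src_chrom, b.src_start, b.src_end, b.dst_chrom, b.dst_start, b.dst_end, b.strand)
                for b in self.blocks
            ],
            columns=SYNTENY_COLUMNS,
        )

    def invert(self) -> "SyntenyMap":
        """Swap source and destination. Valid when fragments are disjoint on
        the destination as well (true for genome-tiling karyotype maps)."""
        return SyntenyMap(
            SyntenyBlock(b.dst_chrom, b.dst_start, b.dst_end, b.src_chrom, b.src_start, b.src_end, b.strand)
            for b in self.blocks
        )

    # ---- queries -------------------------------------------------------
    def overlapping_blocks(self, chrom: str, start: int, end: int) -> list[SyntenyBlock]:
        if chrom not in self._by_chrom:
            return []
        starts, ends, blist = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return blist[lo:hi]

    def project_region(
        self, chrom: str, start: int, end: int, warn_unmapped: bool = True
    ) -> tuple[list[dict], list[tuple[int, int]]]:
        """Project a source region, fragment by fragment.

        Returns (mapped, unmapped): ``mapped`` is an ordered list of dicts
        with destination chrom/start/end, strand, and the source fragment
        that produced each piece; ``unmapped`` lists the source sub-intervals
        falling in inter-fragment gaps. Inverted fragments yield destination
        intervals with start < end (endpoints swapped after projection).
        """
        if end <= start:
            raise ValueError(f"empty region {chrom}:{start}-{end}")
        blocks = self.overlapping_blocks(chrom, start, end)
        if not blocks:
            if warn_unmapped:
                warnings.warn(f"region {chrom}:{start}-{end} has no syntenic fragment; fully unmapped")
            return [], [(start, end)]
        mapped: list[dict] = []
        unmapped: list[tuple[int, int]] = []
        cursor = start
        for b in blocks:
            cs, ce = max(start, b.src_start), min(end, b.src_end)
            if cs > cursor:
                unmapped.append((cursor, cs))
            p1 = project_coordinate(b, cs)
            p2 = project_coordinate(b, ce)
            d1, d2 = (p1, p2) if p1 <= p2 else (p2, p1)
            if d2 > d1:
                mapped.append(
                    {
                        "dst_chrom": b.dst_chrom,
                        "dst_start": d1,
                        "dst_end": d2,
                        "strand": b.strand,
                        "src_fragment": f"{b.src_chrom}:{b.src_start}-{b.src_end}({b.strand})",
                    }
                )
            cursor = ce
        if cursor < end:
            unmapped.append((cursor, end))
        return mapped, unmapped

    def compose(self, other: "SyntenyMap") -> "SyntenyMap":
        """Compose self (A->B) with ``other`` (B->C) into an A->C map.

        Each fragment's destination interval is pushed through ``other`` and
        the matching source sub-intervals are recovered by the same linear
        scaling; exact for length-preserving fragments, nearest-bp otherwise.
        """
        out: list[SyntenyBlock] = []
        for b in self.blocks:
            for frag in other.overlapping_blocks(b.dst_chrom, b.dst_start, b.dst_end):
                m1, m2 = max(b.dst_start, frag.src_start), min(b.dst_end, frag.src_end)
                if m2 <= m1:
                    continue
                d1, d2 = project_coordinate(frag, m1), project_coordinate(frag, m2)
                c1, c2 = min(d1, d2), max(d1, d2)
                rho = b.src_length / b.dst_length
                if b.strand == "+":
                    s1 = b.src_start + (m1 - b.dst_start) * rho
                    s2 = b.src_start + (m2 - b.dst_start) * rho
                else:
                    s1 = b.src_start + (b.dst_end - m2) * rho
                    s2 = b.src_start + (b.dst_end - m1) * rho
                strand = "+" if b.strand == frag.strand else "-"
                a1, a2 = _round_half_up(s1), _round_half_up(s2)
                if a2 > a1 and c2 > c1:
                    out.append(SyntenyBlock(b.src_chrom, a1, a2, frag.dst_chrom, c1, c2, strand))
        return SyntenyMap(out)


def lift_interval(
    region: tuple[str, int, int], blocks: SyntenyMap | Sequence[SyntenyBlock]
) -> tuple[list[dict], list[tuple[int, int]]]:
    """Lift a (chrom, start, end) region through a pairwise synteny map.

    Same contract as :meth:`SyntenyMap.project_region`; accepts a raw block
    sequence for convenience.
    """
    smap = blocks if isinstance(blocks, SyntenyMap) else SyntenyMap(blocks)
    return smap.project_region(*region)


def identity_map(chrom_sizes: dict[str, int]) -> SyntenyMap:
    """Identity synteny (each chromosome maps onto itself, '+')."""
    return SyntenyMap(
        SyntenyBlock(c, 0, length, c, 0, length, "+") for c, length in chrom_sizes.items()
    )
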