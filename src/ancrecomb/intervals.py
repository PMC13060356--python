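"""Low-level genomic interval arithmetic.

All coordinates are 0-based, half-open (BED convention). Interval tables are
pandas DataFrames carrying at least ``chrom``, ``start`` and ``end`` columns.
Most helpers assume intervals are sorted by (chrom, start) and non-overlapping
within a chromosome — the natural state of window tracks — and say so when
they do.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy sorted by (chrom, start, end)."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> None:
    """Raise ``ValueError`` on negative-length or malformed intervals."""
    if not set(BED_COLUMNS) <= set(df.columns):
        raise ValueError(f"{name} must have columns {BED_COLUMNS}, got {list(df.columns)}")
    if len(df) and (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"{name}: empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")


class IntervalIndex:
    """Overlap queries against sorted, non-overlapping intervals.

    Built once per chromosome from a window-style table; a query returns the
    positional row slice of intervals overlapping a half-open query interval.
    Because the indexed intervals never overlap each other, binary search on
    the start/end arrays is sufficient (no interval tree needed).
    """

    def __init__(self, df: pd.DataFrame):
        validate_intervals(df)
        self.df = sort_intervals(df)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"intervals on {chrom} overlap; IntervalIndex requires disjoint intervals")
            self._by_chrom[chrom] = (starts, ends, sub.index.to_numpy())

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row labels (into the sorted table) of intervals overlapping [start, end)."""
        if chrom not in self._by_chrom:
            return np.empty(0, dtype=int)
        starts, ends, idx = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        return idx[lo:hi]

    def chroms(self) -> list[str]:
        return list(self._by_chrom)


def merge_adjacent(intervals: Sequence[tuple[int, int]], max_gap: int = 0) -> list[tuple[int, int]]:
    """Merge sorted (start, end) pairs whose inter-interval gap is <= max_gap."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_adjacent(list(intervals)))


def interval_jaccard(
    a: Sequence[tuple[str, int, int]], b: Sequence[tuple[str, int, int]]
) -> float:
    """Jaccard index (intersection bp / union bp) of two interval sets.

    Each argument is a sequence of (chrom, start, end). Returns 0.0 when the
    union is empty.
    """
    by_chrom_a: dict[str, list[tuple[int, int]]] = {}
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in a:
        by_chrom_a.setdefault(c, []).append((s, e))
    for c, s, e in b:
        by_chrom_b.setdefault(c, []).append((s, e))
    inter = 0
    union = 0
    for chrom in set(by_chrom_a) | set(by_chrom_b):
        ia = merge_adjacent(by_chrom_a.get(chrom, []))
        ib = merge_adjacent(by_chrom_b.get(chrom, []))
        union += _union_length(ia + ib)
        # two-pointer sweep over merged, disjoint interval lists
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                inter += e - s
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
    return inter / union if union else 0.0


def weighted_quantile(values: np.ndarray, weights: np.ndarray, qs: Sequence[float]) -> np.ndarray:
    """Quantiles of a discrete distribution where value[i] has mass weights[i].

    Equivalent to quantiles of ``np.repeat(values, weights)`` (inverse-CDF
    definition) without materialising the expansion; used for per-base score
    summaries over megabase regions.
    """
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w)
    total = cw[-1]
    out = np.empty(len(qs))
    for k, q in enumerate(qs):
        target = q * total
        i = int(np.searchsorted(cw, target, side="left"))
        out[k] = v[min(i, len(v) - 1)]
    return out
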