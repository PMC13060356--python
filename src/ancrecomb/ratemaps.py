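"""Recombination-map windowing and genome-wide quartile categorisation.

A per-species recombination landscape arrives as an interval track of rate
estimates (e.g. the output of a population-genomic rate inference). This
module post-processes such tracks the way comparative recombination studies
do: optional sliding-block smoothing, tiling each chromosome into fixed
windows (1.5 Mb by default), averaging rates into the windows, zero-filling
known data-free deserts, and ranking every window genome-wide into four rate
quartiles (Q1 = lowest, Q4 = highest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalIndex, sort_intervals, validate_intervals

CATEGORIES = ("Q1", "Q2", "Q3", "Q4")

DEFAULT_WINDOW_SIZE = 1_500_000
DEFAULT_BLOCK = 2_000_000
DEFAULT_STEP = 50_000


@dataclass
class RecombinationMap:
    """Ordered, non-overlapping rate intervals for one species.

    ``windows`` has columns (chrom, start, end, rate); NaN rate means no
    data. Negative rates are invalid.
    """

    species: str
    windows: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        validate_intervals(self.windows, f"{self.species} rate track")
        self.windows = sort_intervals(self.windows)
        rates = self.windows["rate"]
        if (rates.dropna() < 0).any():
            raise ValueError(f"{self.species}: negative recombination rate")

    def n_rated(self) -> int:
        return int(self.windows["rate"].notna().sum())


@dataclass
class QuartileTrack:
    """Window-level rate categories for one species (Q1 lowest ... Q4 highest)."""

    species: str
    entries: pd.DataFrame  # chrom, start, end, category (NA = uncategorised)
    provenance: str = ""

    def counts(self) -> dict[str, int]:
        return {c: int((self.entries["category"] == c).sum()) for c in CATEGORIES}


def make_windows(chrom_sizes: Mapping[str, int], size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Tile each chromosome into consecutive half-open windows of ``size`` bp.

    The terminal window is truncated at the chromosome end and retained.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        for start in range(0, length, size):
            rows.append((chrom, start, min(start + size, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def sliding_average(
    raw: RecombinationMap,
    block: int = DEFAULT_BLOCK,
    step: int = DEFAULT_STEP,
    chrom_sizes: Mapping[str, int] | None = None,
) -> RecombinationMap:
    """Average a raw rate track into overlapping blocks on a sliding start grid.

    Blocks start at every multiple of ``step`` and span ``block`` bp
    (truncated at the chromosome end); each block carries the unweighted mean
    of the raw interval values overlapping it. Mirrors the standard
    "2 Mb blocks with 50 kb sliding windows" post-processing of inferred
    recombination maps.
    """
    if not (block >= step > 0):
        raise ValueError("need block >= step > 0")
    out = []
    for chrom, sub in raw.windows.groupby("chrom", sort=False):
        length = chrom_sizes[chrom] if chrom_sizes else int(sub["end"].max())
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["rate"].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        cum_sum = np.concatenate([[0.0], np.cumsum(np.where(ok, vals, 0.0))])
        cum_n = np.concatenate([[0], np.cumsum(ok.astype(int))])
        block_starts = np.arange(0, length, step)
        block_ends = np.minimum(block_starts + block, length)
        lo = np.searchsorted(ends, block_starts, side="right")
        hi = np.searchsorted(starts, block_ends, side="left")
        n = cum_n[hi] - cum_n[lo]
        with np.errstate(invalid="ignore"):
            means = np.where(n > 0, (cum_sum[hi] - cum_sum[lo]) / np.maximum(n, 1), np.nan)
        out.append(pd.DataFrame({"chrom": chrom, "start": block_starts, "end": block_ends, "rate": means}))
    windows = (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=["chrom", "start", "end", "rate"])
    )
    return RecombinationMap(raw.species, windows, provenance=f"{raw.provenance}|sliding({block},{step})")


def map_rates_to_windows(
    rmap: RecombinationMap,
    windows: pd.DataFrame,
    length_weighted: bool = False,
) -> RecombinationMap:
    """Average source-interval rates into target windows.

    Default is the unweighted mean over every source interval overlapping the
    window (the common behaviour of interval-map tooling); set
    ``length_weighted`` to weight by overlap length instead. Windows with no
    overlapping rated interval become missing (NaN).
    """
    validate_intervals(windows, "windows")
    index = IntervalIndex(rmap.windows)
    src = index.df
    starts = src["start"].to_numpy()
    ends = src["end"].to_numpy()
    vals = src["rate"].to_numpy(dtype=float)
    out = sort_intervals(windows[["chrom", "start", "end"]]).copy()
    missing_chroms = sorted(set(out["chrom"]) - set(index.chroms()))
    if missing_chroms:
        warnings.warn(f"{rmap.species}: no rate data for chromosome(s) {missing_chroms}; windows left missing")
    rates = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        rows = index.query(row.chrom, row.start, row.end)
        if len(rows) == 0:
            continue
        v = vals[rows]
        keep = ~np.isnan(v)
        if not keep.any():
            continue
        if length_weighted:
            w = np.minimum(ends[rows], row.end) - np.maximum(starts[rows], row.start)
            w = w[keep].astype(float)
            rates[i] = float(np.average(v[keep], weights=w))
        else:
            rates[i] = float(np.mean(v[keep]))
    out["rate"] = rates
    return RecombinationMap(rmap.species, out, provenance=f"{rmap.provenance}|windowed")


def fill_desert_zero(rmap: RecombinationMap, desert_regions: pd.DataFrame) -> RecombinationMap:
    """Set missing rates to 0 inside known recombination deserts.

    Windows overlapping a desert region and lacking data get rate 0 (the
    desert is asserted to recombine at a negligible rate); windows with data
    are untouched, as are missing windows outside the deserts.
    """
    validate_intervals(desert_regions, "desert_regions")
    out = rmap.windows.copy()
    desert_idx = IntervalIndex(desert_regions[["chrom", "start", "end"]])
    for i, row in enumerate(out.itertuples(index=False)):
        if np.isnan(row.rate) and len(desert_idx.query(row.chrom, row.start, row.end)):
            out.iat[i, out.columns.get_loc("rate")] = 0.0
    return RecombinationMap(rmap.species, out, provenance=f"{rmap.provenance}|desert0")


def assign_quartiles(rmap: RecombinationMap) -> QuartileTrack:
    """Rank windows genome-wide by rate and split into four equal categories.

    Windows are sorted from highest to lowest rate (ties broken by genomic
    coordinate for determinism) and divided into four groups; when the count
    is not divisible by four the extra windows go to the highest categories.
    Q1 holds the lowest rates, Q4 the highest. Missing windows receive no
    category. Requires at least four rated windows.
    """
    win = rmap.windows.copy()
    rated = win[win["rate"].notna()]
    n = len(rated)
    if n < 4:
        raise ValueError(f"{rmap.species}: need >= 4 rated windows to form quartiles, have {n}")
    if rated["rate"].nunique() == 1:
        warnings.warn(
            f"{rmap.species}: all rated windows share one rate; quartiles are set by coordinate tie-break only"
        )
    order = rated.sort_values(["rate", "chrom", "start"], ascending=[False, True, True], kind="mergesort")
    base, rem = divmod(n, 4)
    sizes = {  # highest categories absorb the remainder
        "Q4": base + (1 if rem >= 1 else 0),
        "Q3": base + (1 if rem >= 2 else 0),
        "Q2": base + (1 if rem >= 3 else 0),
        "Q1": base,
    }
    labels = []
    for cat in ("Q4", "Q3", "Q2", "Q1"):
        labels.extend([cat] * sizes[cat])
    win["category"] = pd.Series(pd.NA, index=win.index, dtype="string")
    win.loc[order.index, "category"] = labels
    entries = win[["chrom", "start", "end", "category"]]
    return QuartileTrack(rmap.species, entries, provenance=f"{rmap.provenance}|quartiles")
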