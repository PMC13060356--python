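"""Comparing called regions against planted ground truth.

Used by the test-suite and the end-of-run report: per-planted-region best
Jaccard overlap with same-class calls on the reference genome, plus a
category-shuffling helper that provides an empirical null for the caller.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .conserved import ConservedCall
from .intervals import interval_jaccard
from .ratemaps import QuartileTrack
from .simulate import GroundTruth


def planted_recovery(
    truth: GroundTruth,
    alr_calls: Sequence[ConservedCall],
    ahr_calls: Sequence[ConservedCall],
    species: str,
    jaccard_threshold: float = 0.5,
) -> pd.DataFrame:
    """Best same-class call Jaccard for every planted region, on ``species`` coordinates."""
    calls = {"ALR": list(alr_calls), "AHR": list(ahr_calls)}
    rows = []
    for p in truth.planted:
        target = [(c, s, e) for c, s, e in p.species_intervals[species]]
        best = 0.0
        for call in calls[p.region_class]:
            best = max(best, interval_jaccard(target, [call.interval()]))
        rows.append((p.region_class, p.anc_chrom, p.start, p.end, best, best >= jaccard_threshold))
    return pd.DataFrame(
        rows, columns=["region_class", "anc_chrom", "start", "end", "best_jaccard", "recovered"]
    )


def recovery_rate(recovery: pd.DataFrame) -> float:
    return float(recovery["recovered"].mean()) if len(recovery) else float("nan")


def shuffle_track_categories(track: QuartileTrack, seed: int) -> QuartileTrack:
    """Permute the categories of the categorised windows (empirical null).

    Window coordinates stay fixed; the spatial arrangement of rate
    categories — the entire signal the caller relies on — is destroyed while
    each quartile keeps its exact genome-wide share.
    """
    rng = np.random.default_rng(seed)
    entries = track.entries.copy()
    mask = entries["category"].notna()
    values = entries.loc[mask, "category"].to_numpy()
    entries.loc[mask, "category"] = rng.permutation(values)
    return QuartileTrack(track.species, entries, provenance=f"{track.provenance}|shuffled({seed})")
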