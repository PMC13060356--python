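"""Pathway skew testing between high- and low-recombining gene sets.

For each pathway (gene set) the classified genes form a 2x2 contingency
table — pathway membership against high/low recombination class — tested
with Pearson's chi-squared (df = 1, no continuity correction) and corrected
across pathways by the Benjamini–Hochberg step-up procedure. The 2x2
pathway-versus-rest design lets pathway size enter the expected counts,
which is what "controlling for pathway size" amounts to here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SkewTable:
    """2x2 counts: a=pathway&high, b=pathway&low, c=rest&high, d=rest&low."""

    pathway: str
    a: int
    b: int
    c: int
    d: int

    @property
    def ratio(self) -> float:
        """a/b, reported as inf when the pathway has no low-class genes."""
        return self.a / self.b if self.b else math.inf


def pathway_counts(
    high_set: Iterable[str],
    low_set: Iterable[str],
    pathways: Mapping[str, Sequence[str]],
) -> tuple[list[SkewTable], list[str]]:
    """Build per-pathway 2x2 tables against the classified gene pool.

    Genes outside ``high_set`` and ``low_set`` are ignored; pathways with no
    classified member are skipped and logged. The two sets must be disjoint.
    """
    high = set(high_set)
    low = set(low_set)
    both = high & low
    if both:
        raise ValueError(f"{len(both)} gene(s) in both the high and low set, e.g. {sorted(both)[:3]}")
    n_high, n_low = len(high), len(low)
    tables: list[SkewTable] = []
    skipped: list[str] = []
    for name, members in pathways.items():
        mem = set(members)
        a = len(mem & high)
        b = len(mem & low)
        if a + b == 0:
            skipped.append(name)
            continue
        tables.append(SkewTable(name, a, b, n_high - a, n_low - b))
    return tables, skipped


def skew_test(table: SkewTable) -> tuple[float, float, str]:
    """Pearson chi-squared (df=1, no continuity correction) on one 2x2 table.

    Returns (chi2, p, direction); direction is 'high' when the pathway's
    high fraction exceeds the background's, 'low' when below, 'none' at
    equality. A zero margin makes the table untestable (ValueError).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError(f"{table.pathway}: zero margin, chi-squared undefined")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    frac_path = a / (a + b)
    frac_rest = c / (c + d)
    direction = "high" if frac_path > frac_rest else ("low" if frac_path < frac_rest else "none")
    return float(chi2), float(p), direction


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_bh, _, _ = multipletests(p, method="fdr_bh")
    return p_bh


def analyze_pathway_skew(
    high_set: Iterable[str],
    low_set: Iterable[str],
    pathways: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full skew analysis: counts, chi-squared, BH correction, direction.

    The returned table is sorted by adjusted p; ``direction`` is set to
    'none' for pathways whose adjusted p fails the ``alpha`` threshold.
    Pathways whose table has a zero margin are flagged untestable and
    excluded from the correction.
    """
    tables, skipped = pathway_counts(high_set, low_set, pathways)
    rows = []
    testable: list[int] = []
    for i, t in enumerate(tables):
        try:
            chi2, p, direction = skew_test(t)
            testable.append(i)
        except ValueError:
            chi2, p, direction = np.nan, np.nan, "untestable"
        rows.append([t.pathway, t.a, t.b, t.c, t.d, t.ratio, chi2, p, np.nan, direction])
    df = pd.DataFrame(
        rows,
        columns=["pathway", "a", "b", "c", "d", "ratio", "chi2", "p", "p_bh", "direction"],
    )
    if testable:
        df.loc[testable, "p_bh"] = bh_adjust(df.loc[testable, "p"].to_numpy())
        fail = df.index.isin(testable) & (df["p_bh"] >= alpha)
        df.loc[fail, "direction"] = "none"
    for name in skipped:
        df.loc[len(df)] = [name, 0, 0, len(set(high_set)), len(set(low_set)),
                           np.nan, np.nan, np.nan, np.nan, "skipped"]
    return df.sort_values("p_bh", na_position="last").reset_index(drop=True)
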