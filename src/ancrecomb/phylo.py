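"""Alignment filtering, column subsampling, tree comparison, and
conservation-score aggregation for the region-phylogenomics comparison.

The workflow these pieces serve: extract alignments for conserved low- and
high-recombining regions, drop columns with more than 10% missing data,
subsample a fixed number of columns, infer a tree per dataset (delegated to
an external/third-party fitter — a distance-based neighbour-joining helper
is provided), and compare branch lengths and node heights between the two
trees. Per-base conservation scores (e.g. PhyloP, positive = conserved) are
summarised over region coordinates separately.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj

from .intervals import weighted_quantile

DEFAULT_MISSING = "-N?"


@dataclass
class Alignment:
    """A character matrix (taxa x columns) over {A,C,G,T} plus missing symbols."""

    taxa: list[str]
    matrix: np.ndarray  # dtype '<U1', shape (n_taxa, n_columns)
    positions: np.ndarray | None = None  # original column coordinates

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon names")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa")
        if self.positions is None:
            self.positions = np.arange(self.matrix.shape[1])

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError("unequal sequence lengths; not an alignment")
        taxa = [r.id for r in records]
        matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
        return cls(taxa, matrix)

    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=taxon, description="")
            for taxon, row in zip(self.taxa, self.matrix)
        ]
        SeqIO.write(records, path, "fasta")


def missingness_per_column(aln: Alignment, missing_symbols: str = DEFAULT_MISSING) -> np.ndarray:
    symbols = set(missing_symbols.upper()) | set(missing_symbols.lower())
    mask = np.isin(aln.matrix, list(symbols))
    return mask.mean(axis=0)


def filter_columns_by_missingness(
    aln: Alignment, threshold: float = 0.10, missing_symbols: str = DEFAULT_MISSING
) -> Alignment:
    """Keep columns whose missing fraction is <= threshold (strictly greater removed)."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    if aln.n_columns == 0:
        return Alignment(aln.taxa, aln.matrix.copy(), aln.positions.copy())
    keep = missingness_per_column(aln, missing_symbols) <= threshold
    return Alignment(aln.taxa, aln.matrix[:, keep], aln.positions[keep])


def subsample_columns(aln: Alignment, n: int, seed: int) -> Alignment:
    """Sample ``n`` distinct columns uniformly, emitted in genomic order."""
    if n > aln.n_columns:
        raise ValueError(f"cannot sample {n} of {aln.n_columns} columns")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(aln.n_columns, size=n, replace=False))
    return Alignment(aln.taxa, aln.matrix[:, chosen], aln.positions[chosen])


# ---------------------------------------------------------------------------
# tree comparison


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def _leafset(node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _bipartition_key(clade: frozenset[str], all_taxa: frozenset[str], anchor: str) -> frozenset[str]:
    # canonical side: the one not containing the anchor taxon (rooting-invariant)
    return frozenset(all_taxa - clade) if anchor in clade else clade


def compare_trees(tree_a, tree_b) -> dict:
    """Pair branches and node heights between two trees on shared taxa.

    Branches are matched by the taxon bipartition they induce (restricted to
    the shared taxon set, so the comparison is invariant to rooting); node
    heights — root-to-node path lengths — are matched by identical descendant
    clades and therefore depend on each tree's given root. Returns a dict
    with ``branches`` and ``heights`` DataFrames plus a ``summary`` of the
    median B/A branch-length ratio and match counts.
    """
    ta, tb = _as_tree(tree_a), _as_tree(tree_b)
    taxa_a = {leaf.taxon.label for leaf in ta.leaf_node_iter()}
    taxa_b = {leaf.taxon.label for leaf in tb.leaf_node_iter()}
    shared = taxa_a & taxa_b
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared taxa, have {len(shared)}")
    anchor = min(shared)
    all_shared = frozenset(shared)

    def edge_table(tree, own_taxa):
        sub = tree.clone(depth=1)
        if own_taxa - shared:
            sub.retain_taxa_with_labels(sorted(shared))
        branches: dict[frozenset[str], float] = {}
        clades: dict[frozenset[str], float] = {}
        for node in sub.preorder_node_iter():
            clade = _leafset(node)
            if not clade or clade == all_shared:
                clades[clade] = float(node.distance_from_root() or 0.0)
                continue
            key = _bipartition_key(clade, all_shared, anchor)
            length = float(node.edge.length or 0.0)
            branches[key] = branches.get(key, 0.0) + length
            clades[clade] = float(node.distance_from_root() or 0.0)
        return branches, clades

    br_a, cl_a = edge_table(ta, taxa_a)
    br_b, cl_b = edge_table(tb, taxa_b)
    shared_keys = sorted(set(br_a) & set(br_b), key=sorted)
    if not shared_keys:
        warnings.warn("no shared clades between the two trees")
    branch_rows = []
    for key in shared_keys:
        la, lb = br_a[key], br_b[key]
        branch_rows.append(
            ("|".join(sorted(key)), la, lb, lb - la, lb / la if la > 0 else np.nan)
        )
    branches = pd.DataFrame(branch_rows, columns=["clade", "length_a", "length_b", "diff", "ratio"])
    height_keys = sorted(set(cl_a) & set(cl_b), key=sorted)
    heights = pd.DataFrame(
        [("|".join(sorted(k)), cl_a[k], cl_b[k], cl_b[k] - cl_a[k]) for k in height_keys],
        columns=["clade", "height_a", "height_b", "diff"],
    )
    ratios = branches["ratio"].dropna()
    summary = {
        "n_shared_branches": len(branches),
        "n_unmatched_a": len(set(br_a) - set(br_b)),
        "n_unmatched_b": len(set(br_b) - set(br_a)),
        "median_ratio": float(ratios.median()) if len(ratios) else np.nan,
        "median_branch_diff": float(branches["diff"].median()) if len(branches) else np.nan,
        "median_height_diff": float(heights["diff"].median()) if len(heights) else np.nan,
    }
    return {"branches": branches, "heights": heights, "summary": summary}


# ---------------------------------------------------------------------------
# distance-based tree fitting (independent of any simulator internals)


def jc_distance_matrix(aln: Alignment, missing_symbols: str = DEFAULT_MISSING, max_distance: float = 10.0) -> DistanceMatrix:
    """Jukes–Cantor corrected pairwise distances, ignoring missing cells."""
    symbols = set(missing_symbols.upper()) | set(missing_symbols.lower())
    present = ~np.isin(aln.matrix, list(symbols))
    n = len(aln.taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = present[i] & present[j]
            if not ok.any():
                d = max_distance
            else:
                p = float(np.mean(aln.matrix[i, ok] != aln.matrix[j, ok]))
                d = max_distance if p >= 0.75 else min(-0.75 * np.log(1 - 4 * p / 3), max_distance)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=aln.taxa)


def nj_tree(aln: Alignment) -> str:
    """Neighbour-joining tree (newick) from JC-corrected distances.

    Negative branch-length estimates are clamped to zero.
    """
    tree = nj(jc_distance_matrix(aln))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# conservation scores over regions


def scores_in_regions(track: pd.DataFrame, regions: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Summarise a per-base score track over a set of regions.

    ``track`` is a bedGraph-style table (chrom, start, end, value) of sorted,
    non-overlapping intervals; ``regions`` a BED-style table. Each base is
    counted once per region containing it. Returns a per-region table with
    n (bases with data), mean, median and quartiles, plus the pooled
    distribution over all regions.
    """
    from .intervals import IntervalIndex

    index = IntervalIndex(track[["chrom", "start", "end"]].assign(value=track["value"].to_numpy()))
    vals = index.df["value"].to_numpy(dtype=float)
    starts = index.df["start"].to_numpy()
    ends = index.df["end"].to_numpy()
    rows = []
    pooled_v: list[np.ndarray] = []
    pooled_w: list[np.ndarray] = []
    for k, row in enumerate(regions.itertuples(index=False)):
        name = getattr(row, "name", f"region_{k}")
        hits = index.query(row.chrom, row.start, row.end)
        if len(hits) == 0:
            rows.append((name, row.chrom, row.start, row.end, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        w = np.minimum(ends[hits], row.end) - np.maximum(starts[hits], row.start)
        v = vals[hits]
        keep = (w > 0) & ~np.isnan(v)
        v, w = v[keep], w[keep]
        if len(v) == 0:
            rows.append((name, row.chrom, row.start, row.end, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        q25, med, q75 = weighted_quantile(v, w, [0.25, 0.5, 0.75])
        rows.append((name, row.chrom, row.start, row.end, int(w.sum()), float(np.average(v, weights=w)), med, q25, q75))
        pooled_v.append(v)
        pooled_w.append(w)
    per_region = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "n", "mean", "median", "q25", "q75"]
    )
    if pooled_v:
        pv = np.concatenate(pooled_v)
        pw = np.concatenate(pooled_w)
        q25, med, q75 = weighted_quantile(pv, pw, [0.25, 0.5, 0.75])
        pooled = {"n": int(pw.sum()), "mean": float(np.average(pv, weights=pw)), "median": float(med), "q25": float(q25), "q75": float(q75)}
    else:
        pooled = {"n": 0, "mean": np.nan, "median": np.nan, "q25": np.nan, "q75": np.nan}
    return per_region, pooled
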