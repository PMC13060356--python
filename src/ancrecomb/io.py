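"""Readers and writers for the plain-text genomics formats used throughout.

Formats: chromosome-size TSV, bedGraph, BED, synteny-block TSV, GMT gene
sets, and a minimal gene-level GFF3. All coordinates on disk follow each
format's own convention (bedGraph/BED 0-based half-open, GFF3 1-based
closed); in memory everything is 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

SYNTENY_COLUMNS = ["src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end", "strand"]


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    sizes = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
    for chrom, length in sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bedgraph(path: str) -> pd.DataFrame:
    """Read a bedGraph track into (chrom, start, end, value); '.' -> NaN."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str}, na_values=["."],
        skiprows=_track_header_rows(path),
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["value"] = pd.to_numeric(df["value"])
    return df


def _track_header_rows(path: str) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(df: pd.DataFrame, path: str, value_col: str = "value", header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        for row in df.itertuples(index=False):
            value = getattr(row, value_col)
            text = "." if pd.isna(value) else format(float(value), ".6g")
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{text}\n")


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3-6; extra columns named name/score/strand when present."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str, header: str | None = None) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_synteny(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SYNTENY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"synteny table {path} lacks columns {sorted(missing)}")
    return df[SYNTENY_COLUMNS]


def write_synteny(df: pd.DataFrame, path: str) -> None:
    df[SYNTENY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT file: one gene set per line (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected >=3 tab-separated fields")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_gff3_genes(genes: pd.DataFrame, path: str, source: str = "ancrecomb") -> None:
    """Write gene records (chrom, start, end, symbol[, strand]) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            strand = getattr(row, "strand", "+")
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{int(row.start) + 1}\t{int(row.end)}\t.\t{strand}\t.\t"
                f"ID=gene-{row.symbol};Name={row.symbol}\n"
            )


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Read gene features from GFF3 into a 0-based half-open gene table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            symbol = attrs.get("Name") or attrs.get("ID", "").removeprefix("gene-")
            rows.append((f[0], int(f[3]) - 1, int(f[4]), symbol, f[6]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol", "strand"])


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
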