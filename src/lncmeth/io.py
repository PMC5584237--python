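"""Readers and writers for every external file the pipeline touches.

All genomic coordinates are 0-based half-open internally; GTF's 1-based
closed convention is converted at the boundary (pyranges does this on
read).  Readers validate strictly and raise :class:`FormatError` rather
than silently coercing malformed input; writers emit deterministic byte
streams for equal inputs (sorted, fixed float formatting).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

__all__ = [
    "AnnotationRecord",
    "FormatError",
    "read_annotation",
    "read_matrix",
    "write_matrix",
    "read_interactions",
    "read_clinical",
    "read_probe_manifest",
    "read_sample_groups",
    "read_term_table",
    "read_edge_table",
    "write_network",
    "read_network",
    "write_promoters_bed",
]


class FormatError(ValueError):
    """Malformed external file content."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-level annotation entry (0-based half-open coordinates)."""

    feature_id: str
    feature_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"{self.feature_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.feature_id}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: `start` on +, `end` on - strand."""
        return self.start if self.strand == "+" else self.end


def read_annotation(path, biotype: str | None = None) -> list[AnnotationRecord]:
    """Read gene-level records from a GTF-style file.

    Only ``gene`` feature lines are kept.  Coordinates are converted from
    GTF 1-based closed to 0-based half-open.  Records with a strand other
    than ``+``/``-`` are rejected with a warning; a missing ``gene_id``
    attribute is a parse error naming the offending row.
    """
    import pyranges as pr

    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        return []
    gr = pr.read_gtf(str(path))
    df = gr.df
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: no gene_id attribute in any record")
    df = df[df["Feature"].astype(str) == "gene"]
    records: list[AnnotationRecord] = []
    for idx, row in df.iterrows():
        gid = row.get("gene_id")
        if gid is None or (isinstance(gid, float) and np.isnan(gid)) or gid == "":
            raise FormatError(f"{path}: record {idx + 1} lacks a gene_id attribute")
        strand = str(row["Strand"])
        if strand not in {"+", "-"}:
            warnings.warn(
                f"{path}: record {idx + 1} ({gid}) has unknown strand {strand!r}; skipped",
                stacklevel=2,
            )
            continue
        bt = row.get("gene_type", "") or row.get("gene_biotype", "") or ""
        if biotype is not None and bt != biotype:
            continue
        name = row.get("gene_name", "") or str(gid)
        records.append(
            AnnotationRecord(
                feature_id=str(gid),
                feature_name=str(name),
                chrom=str(row["Chromosome"]),
                start=int(row["Start"]),
                end=int(row["End"]),
                strand=strand,
                biotype=str(bt),
            )
        )
    return records


def _validate_rectangular(path: Path) -> None:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        width = None
        for i, row in enumerate(reader):
            if not row:
                continue
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: ragged row {i + 1} ({len(row)} fields, expected {width})"
                )


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples TSV matrix.

    First column holds feature ids, header row holds sample ids.  The
    missing-value token is ``NA``.  Duplicate feature ids and non-numeric
    cells are errors.
    """
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False
    )
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate feature id(s): {', '.join(map(str, dup))}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a features x samples matrix as TSV (missing values as ``NA``)."""
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="feature_id")


def read_interactions(path) -> pd.DataFrame:
    """Read a (mirna_id, target_id) interaction table; rows deduplicated."""
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"mirna_id", "target_id"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}, got {list(df.columns)}")
    return df[["mirna_id", "target_id"]].drop_duplicates().reset_index(drop=True)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table with columns (sample, time, event)."""
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    need = {"sample", "time", "event"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    df = df[["sample", "time", "event"]].copy()
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "sample"].tolist()
        raise FormatError(f"{path}: non-positive survival time for {bad}")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event indicator must be 0 or 1")
    return df


def read_probe_manifest(path) -> pd.DataFrame:
    """Read a probe manifest with columns (probe_id, chrom, pos)."""
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    need = {"probe_id", "chrom", "pos"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise FormatError(f"{path}: duplicate probe id(s): {dup}")
    df["pos"] = df["pos"].astype(int)
    return df[["probe_id", "chrom", "pos"]]


def read_sample_groups(path) -> pd.Series:
    """Read a sample table (sample_id, group in {tumor, normal})."""
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "group"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    bad = set(df["group"]) - {"tumor", "normal"}
    if bad:
        raise FormatError(f"{path}: unknown group label(s) {sorted(bad)}")
    return df.set_index("sample_id")["group"]


def read_term_table(path, key: str, value: str) -> pd.DataFrame:
    """Read a generic two-or-more-column annotation table (e.g. term->gene)."""
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if key not in df.columns or value not in df.columns:
        raise FormatError(f"{path}: expected columns {key!r} and {value!r}")
    return df.drop_duplicates().reset_index(drop=True)


def read_edge_table(path, child: str = "child", parent: str = "parent") -> pd.DataFrame:
    """Read a directed edge table (e.g. GO ``is_a`` child->parent pairs)."""
    return read_term_table(path, child, parent)


_EDGE_COLUMNS = ["lncrna", "mrna", "pcc", "pcc_p", "shared", "hyper_p"]


def write_network(network: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write a ceRNA network as an edge-list TSV or SIF file.

    Edges are emitted in lexicographic (lncrna, mrna) order so that equal
    networks serialize byte-identically.
    """
    path = Path(path)
    edges = sorted(
        (u, v) if network.nodes[u].get("kind") == "lncrna" else (v, u)
        for u, v in network.edges()
    )
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for u, v in edges:
                d = network.edges[u, v]
                fh.write(
                    f"{u}\t{v}\t{d['pcc']:.10g}\t{d['pcc_p']:.6g}\t"
                    f"{int(d['shared'])}\t{d['hyper_p']:.6g}\n"
                )
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in edges:
                fh.write(f"{u}\tceRNA\t{v}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`write_network`."""
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype={"lncrna": str, "mrna": str})
    if list(df.columns) != _EDGE_COLUMNS:
        raise FormatError(f"{path}: expected columns {_EDGE_COLUMNS}")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.lncrna, kind="lncrna")
        g.add_node(row.mrna, kind="mrna")
        g.add_edge(
            row.lncrna,
            row.mrna,
            pcc=float(row.pcc),
            pcc_p=float(row.pcc_p),
            shared=int(row.shared),
            hyper_p=float(row.hyper_p),
        )
    return g


def write_promoters_bed(promoters: Iterable, path) -> None:
    """Write promoters as BED6 (chrom, start, end, lncRNA id, probe count, strand)."""
    rows = sorted(
        (p.chrom, p.start, p.end, p.lncrna_id, len(p.probe_ids), p.strand)
        for p in promoters
    )
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
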