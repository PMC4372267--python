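"""Genomic data model and flat-file I/O.

All in-memory coordinates are 0-based, half-open ``[start, end)``.
Conversion to and from 1-based closed conventions (GTF) happens only at
the file boundary, so no other module ever needs to reason about
coordinate dialects.

Supported formats: BED3/BED6 (+ narrowPeak-style summit column), BED12,
GTF (UCSC exon-line dialect), bedGraph, and header-carrying TSV tables
for HpaII/MspI site counts and per-replicate FPKM. All outputs are
UTF-8, LF-terminated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SiteCounts",
    "ExpressionTable",
    "ParseError",
    "read_gene_models",
    "read_intervals",
    "write_intervals",
    "write_table",
    "read_site_counts",
    "write_site_counts",
    "read_bedgraph",
    "write_bedgraph",
    "read_peaks",
    "write_peaks",
    "read_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    """Malformed record in a genomic flat file; carries the line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``strand`` defaults to ``"."`` (unknown). ``start < end`` is enforced:
    empty or inverted intervals are rejected at construction, which is what
    lets every downstream consumer assume the half-open invariant.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not isinstance(self.start, (int, np.integer)) or not isinstance(
            self.end, (int, np.integer)
        ):
            raise TypeError("interval bounds must be integers")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require start < end, half-open)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to one exon chain (union over isoforms).

    Exons must be sorted, non-overlapping and contained in ``interval``;
    introns are derived as the within-gene complement of the exons. The
    TSS is the first transcribed base: ``start`` on "+", ``end - 1`` on
    "-". Unstranded genes have no TSS unless explicitly coerced.
    """

    gene_id: str
    biotype: str  # "coding" | "lncRNA"
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if self.biotype not in ("coding", "lncRNA"):
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"exon off-chromosome in {self.gene_id}")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon outside gene interval in {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons overlap or are unsorted in {self.gene_id}")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons[:-1], self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return tuple(out)

    def tss(self, unstranded_as_plus: bool = False) -> int:
        """Transcription start site (0-based position of the first base)."""
        strand = self.strand
        if strand == ".":
            if not unstranded_as_plus:
                raise ValueError(
                    f"gene {self.gene_id} is unstranded; TSS undefined "
                    "(pass unstranded_as_plus=True to coerce)"
                )
            strand = "+"
        return self.interval.start if strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class SiteCounts:
    """HpaII/MspI read counts at one CCGG site for one condition."""

    site: GenomicInterval
    hpaii_count: int
    mspi_count: int
    condition: str

    def __post_init__(self):
        for name in ("hpaii_count", "mspi_count"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


class ExpressionTable:
    """Per-gene, per-condition, per-replicate FPKM values.

    Wraps a long-format DataFrame with columns
    ``gene_id, condition, replicate, fpkm``. All conditions must share the
    same gene universe and FPKM must be non-negative.
    """

    COLUMNS = ["gene_id", "condition", "replicate", "fpkm"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"expression table missing columns {missing}")
        df = df[self.COLUMNS].copy()
        if (df["fpkm"] < 0).any():
            bad = df.loc[df["fpkm"] < 0, "gene_id"].iloc[0]
            raise ValueError(f"negative FPKM (e.g. gene {bad})")
        universes = df.groupby("condition")["gene_id"].apply(frozenset)
        if len(set(universes)) > 1:
            raise ValueError("conditions do not share the same gene universe")
        self.df = df.sort_values(["condition", "replicate", "gene_id"]).reset_index(
            drop=True
        )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene_id"].unique())

    def replicate_matrix(self, condition: str) -> pd.DataFrame:
        """Genes x replicates FPKM matrix for one condition."""
        sub = self.df[self.df["condition"] == condition]
        if sub.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return sub.pivot(index="gene_id", columns="replicate", values="fpkm")

    def condition_mean(self, condition: str) -> pd.Series:
        return self.replicate_matrix(condition).mean(axis=1)

    def to_tsv(self, path) -> None:
        write_table(self.df, path)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# readers / writers


def _open_lines(path):
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _merge_exons(exons: list[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    merged: list[GenomicInterval] = []
    for ex in exons:
        if merged and ex.start <= merged[-1].end:
            last = merged[-1]
            if ex.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, ex.end, last.strand)
        else:
            merged.append(ex)
    return tuple(merged)


def _read_gtf_genes(path, unstranded_as_plus: bool) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    for line_no, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(path, line_no, f"expected 9 GTF fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, line_no, f"non-integer coordinates {start_s},{end_s}")
        if start1 < 1 or end1 < start1:
            raise ParseError(path, line_no, f"invalid 1-based closed span {start1}-{end1}")
        if strand not in VALID_STRANDS:
            raise ParseError(path, line_no, f"invalid strand {strand!r}")
        attr = dict(_GTF_ATTR.findall(attrs))
        gene_id = attr.get("gene_id")
        if not gene_id:
            raise ParseError(path, line_no, "missing gene_id attribute")
        biotype_raw = attr.get("gene_biotype") or attr.get("gene_type") or "protein_coding"
        biotype = "lncRNA" if re.search(r"linc|lnc|noncoding", biotype_raw, re.I) else "coding"
        # GTF is 1-based closed; internal is 0-based half-open.
        ex = GenomicInterval(chrom, start1 - 1, end1, strand)
        rec = per_gene.setdefault(gene_id, {"exons": [], "biotype": biotype, "line": line_no})
        if rec["exons"] and (rec["exons"][0].chrom != chrom or rec["exons"][0].strand != strand):
            raise ParseError(path, line_no, f"gene {gene_id} spans chroms/strands")
        rec["exons"].append(ex)
    genes = []
    for gene_id, rec in per_gene.items():
        exons = _merge_exons(rec["exons"])
        strand = exons[0].strand
        if strand == "." and unstranded_as_plus:
            exons = tuple(
                GenomicInterval(e.chrom, e.start, e.end, "+") for e in exons
            )
            strand = "+"
        interval = GenomicInterval(exons[0].chrom, exons[0].start, exons[-1].end, strand)
        genes.append(GeneModel(gene_id, rec["biotype"], interval, exons))
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def _read_bed12_genes(path, unstranded_as_plus: bool) -> list[GeneModel]:
    genes = []
    for line_no, line in _open_lines(path):
        f = line.split("\t")
        if len(f) < 12:
            raise ParseError(path, line_no, f"expected 12 BED12 fields, got {len(f)}")
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        if strand not in VALID_STRANDS:
            raise ParseError(path, line_no, f"invalid strand {strand!r}")
        if strand == "." and unstranded_as_plus:
            strand = "+"
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(path, line_no, "blockCount does not match block lists")
        if n_blocks == 0:
            raise ParseError(path, line_no, f"zero-exon gene {name}")
        exons = [
            GenomicInterval(chrom, start + bs, start + bs + sz, strand)
            for bs, sz in zip(starts, sizes)
        ]
        try:
            interval = GenomicInterval(chrom, start, end, strand)
            genes.append(GeneModel(name, "coding", interval, _merge_exons(exons)))
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc))
    return genes


def read_gene_models(
    annotation_path,
    dialect: str = "gtf",
    unstranded_as_plus: bool = False,
) -> list[GeneModel]:
    """Read gene models from GTF or BED12, collapsing isoforms per gene_id.

    GTF exon lines (1-based closed) are converted to the internal 0-based
    half-open convention; overlapping exons of different isoforms are merged
    to their union. Genes without exon records are rejected, malformed
    records raise :class:`ParseError` naming the offending line.
    """
    if dialect == "gtf":
        return _read_gtf_genes(annotation_path, unstranded_as_plus)
    if dialect == "bed12":
        return _read_bed12_genes(annotation_path, unstranded_as_plus)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_intervals(path) -> list[GenomicInterval]:
    """Read BED3+ intervals; rejects records violating start < end."""
    out = []
    for line_no, line in _open_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(path, line_no, "need at least 3 BED fields")
        strand = f[5] if len(f) >= 6 else "."
        try:
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
        except (ValueError, TypeError) as exc:
            raise ParseError(path, line_no, str(exc))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a header-carrying TSV (UTF-8, LF) with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=float_format)


def write_site_counts(df: pd.DataFrame, path) -> None:
    """Site-count TSV: chrom, pos, hpaii_count, mspi_count (one condition per file)."""
    cols = ["chrom", "pos", "hpaii_count", "mspi_count"]
    write_table(df[cols], path)


def read_site_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos", "hpaii_count", "mspi_count"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: site-count table needs columns {sorted(need)}")
    if (df[["hpaii_count", "mspi_count"]] < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    """bedGraph (chrom, start, end, score), no header, LF-terminated."""
    df = df[["chrom", "start", "end", "score"]]
    df.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n",
              float_format="%.4f")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "score"], comment="#")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0] + 1
        raise ParseError(path, int(bad), "start >= end in bedGraph record")
    return df


PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "summit"]


def write_peaks(df: pd.DataFrame, path) -> None:
    """BED6+1 peak file; the 7th column is the absolute summit position."""
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    if "summit" not in out.columns:
        out["summit"] = (out["start"] + out["end"]) // 2
    out = out[PEAK_COLUMNS].sort_values(["chrom", "start", "end"])
    out.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


def read_peaks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need at least BED3")
    df = df.iloc[:, : len(PEAK_COLUMNS)]
    df.columns = PEAK_COLUMNS[: df.shape[1]]
    if "summit" not in df.columns:
        df["summit"] = (df["start"] + df["end"]) // 2
    if "strand" not in df.columns:
        df["strand"] = "."
    if (df["start"] >= df["end"]).any():
        bad = int(df.index[df["start"] >= df["end"]][0]) + 1
        raise ParseError(path, bad, "start >= end in peak record")
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into plain strings (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
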