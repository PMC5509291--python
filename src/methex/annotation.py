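"""Strand-aware genomic feature intervals and CpG/region assignment.

Core promoters run from 1 kb upstream to 500 bp downstream of a
transcription start site (TSS), in the direction of transcription; gene
bodies from 1 kb downstream of the TSS to the transcription termination
site (TTS).  Features are classified as CGI when they overlap a CpG-island
interval by at least 1 bp.  All intervals are 1-based closed; BED input is
converted on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .methylome import MergedRegion, chrom_sort_key


class Feature(str, enum.Enum):
    PROMOTER = "promoter"
    GENE_BODY = "gene_body"
    EXON = "exon"
    INTRON = "intron"


class CgiContext(str, enum.Enum):
    CGI = "CGI"
    NON_CGI = "non_CGI"


class ImprintStatus(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNKNOWN = "unknown"
    NONE = "none"


@dataclass
class GeneModel:
    """One gene: TSS/TTS orientation encodes the strand (tss < tts on '+',
    tss > tts on '-'); exons are 1-based closed intervals."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    imprinting_status: ImprintStatus = ImprintStatus.NONE

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tts")
        lo, hi = min(self.tss, self.tts), max(self.tss, self.tts)
        for s, e in self.exons:
            if not (lo <= s <= e <= hi):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")


@dataclass(frozen=True)
class AnnotatedInterval:
    gene_id: str
    feature: Feature
    chrom: str
    start: int
    end: int
    cgi_context: CgiContext = CgiContext.NON_CGI

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id} {self.feature}: start > end")


def promoter_interval(gene: GeneModel, up: int = 1000, down: int = 500) -> AnnotatedInterval:
    """Core promoter: ``up`` bp upstream to ``down`` bp downstream of the
    TSS, in transcription direction; clipped at position 1."""
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    return AnnotatedInterval(gene.gene_id, Feature.PROMOTER, gene.chrom, max(1, start), end)


def gene_body_interval(gene: GeneModel, offset: int = 1000) -> AnnotatedInterval | None:
    """Gene body: ``offset`` bp downstream of the TSS to the TTS; ``None``
    for genes shorter than ``offset``."""
    if abs(gene.tts - gene.tss) < offset:
        return None
    if gene.strand == "+":
        start, end = gene.tss + offset, gene.tts
    else:
        start, end = gene.tts, gene.tss - offset
    return AnnotatedInterval(gene.gene_id, Feature.GENE_BODY, gene.chrom, start, end)


def exon_intron_partition(gene: GeneModel, offset: int = 1000) -> list[AnnotatedInterval]:
    """Clip exons to the gene body and derive introns as the complement;
    the returned intervals tile the gene body exactly.

    Exons falling entirely within the first ``offset`` bp (outside the
    body) are dropped.  Overlapping exons are an error.
    """
    body = gene_body_interval(gene, offset)
    if body is None:
        return []
    exons = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError(f"{gene.gene_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})")
    clipped = []
    for s, e in exons:
        s, e = max(s, body.start), min(e, body.end)
        if s <= e:
            clipped.append((s, e))
    out: list[AnnotatedInterval] = []
    cursor = body.start
    for s, e in clipped:
        if s > cursor:
            out.append(AnnotatedInterval(gene.gene_id, Feature.INTRON, gene.chrom, cursor, s - 1))
        out.append(AnnotatedInterval(gene.gene_id, Feature.EXON, gene.chrom, s, e))
        cursor = e + 1
    if cursor <= body.end:
        out.append(AnnotatedInterval(gene.gene_id, Feature.INTRON, gene.chrom, cursor, body.end))
    return out


def cgi_flag(interval: AnnotatedInterval, cgi_track: Sequence[tuple[str, int, int]]) -> CgiContext:
    """CGI iff the interval overlaps a CpG-island interval by >= 1 bp."""
    for chrom, s, e in cgi_track:
        if chrom == interval.chrom and s <= interval.end and e >= interval.start:
            return CgiContext.CGI
    return CgiContext.NON_CGI


def with_cgi_context(
    intervals: Iterable[AnnotatedInterval], cgi_track: Sequence[tuple[str, int, int]]
) -> list[AnnotatedInterval]:
    """Re-tag each interval with its CGI context against the track."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in cgi_track:
        by_chrom.setdefault(c, []).append((s, e))
    for c in by_chrom:
        by_chrom[c].sort()
    out = []
    for iv in intervals:
        ctx = CgiContext.NON_CGI
        for s, e in by_chrom.get(iv.chrom, ()):
            if s > iv.end:
                break
            if e >= iv.start:
                ctx = CgiContext.CGI
                break
        out.append(AnnotatedInterval(iv.gene_id, iv.feature, iv.chrom, iv.start, iv.end, ctx))
    return out


def assign_to_feature(
    regions: Sequence[MergedRegion], features: Sequence[AnnotatedInterval]
) -> dict[AnnotatedInterval, list[MergedRegion]]:
    """Map each feature to the merged regions with >= 1 member CpG inside it.

    A region may map to several genes' features; regions with no member CpG
    inside a feature are not assigned to it even if their span overlaps.
    """
    by_chrom: dict[str, list[MergedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda r: r.start_pos)
    out: dict[AnnotatedInterval, list[MergedRegion]] = {f: [] for f in features}
    for f in features:
        for r in by_chrom.get(f.chrom, ()):
            if r.start_pos > f.end:
                break
            if r.end_pos < f.start:
                continue
            if any(f.start <= p <= f.end for p in r.member_sites):
                out[f].append(r)
    return out


def cpgs_in_interval(sites: Sequence[tuple[str, int]], interval: AnnotatedInterval) -> list[int]:
    """Indices of (chrom, pos) sites lying within the interval."""
    return [
        i
        for i, (chrom, pos) in enumerate(sites)
        if chrom == interval.chrom and interval.start <= pos <= interval.end
    ]


# ---------------------------------------------------------------------------
# readers


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open) into 1-based closed tuples,
    sorted by chromosome then start."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            out.append((chrom, start + 1, end))
    return sorted(out, key=lambda t: (chrom_sort_key(t[0]), t[1]))


def read_gene_models(path, imprint_lookup: Mapping[str, str] | None = None) -> list[GeneModel]:
    """Read gene models from a flat TSV with columns gene_id, chrom, strand,
    tss, tts, exon_starts, exon_ends (exon lists comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "tss", "tts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    lookup = imprint_lookup or {}
    for _, row in df.iterrows():
        exons: list[tuple[int, int]] = []
        if "exon_starts" in df.columns and isinstance(row.get("exon_starts"), str) and row["exon_starts"]:
            starts = [int(x) for x in row["exon_starts"].rstrip(",").split(",")]
            ends = [int(x) for x in row["exon_ends"].rstrip(",").split(",")]
            exons = list(zip(starts, ends))
        status = ImprintStatus(lookup.get(row["gene_id"], "none"))
        genes.append(
            GeneModel(
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                tss=int(row["tss"]),
                tts=int(row["tts"]),
                exons=exons,
                imprinting_status=status,
            )
        )
    return genes


def read_imprint_lookup(path) -> dict[str, str]:
    """Read a gene_id -> imprint-status TSV lookup."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
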