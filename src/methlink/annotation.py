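"""Genomic interval model, promoter/shore derivation and CGI-gene mapping.

All internal coordinates are 0-based half-open ``[start, end)``.  GTF input
is converted from its native 1-based closed convention on load; BED input is
already 0-based half-open and is taken as is.  Emitted BED is 0-based
half-open.

The central product of this module is the list of :class:`CgiGeneUnit`:
one analysis unit per (CpG island, gene) pair whose CGI overlaps the gene's
promoter, the unit on which the methylation-expression screen operates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")

#: feature labels produced by :func:`classify_site_feature`
FEATURE_LABELS = ("promoter", "gene_body", "CGI", "shore", "intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersect_len(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def _merge_intervals(ivs: Sequence[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Sort and merge overlapping/adjacent intervals on one chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda x: (x.start, x.end)):
        if merged and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return tuple(merged)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with TSS/TES and (merged, sorted) exons.

    The TSS is the strand-dependent 5' end: ``interval.start`` on the +
    strand, ``interval.end - 1`` on the - strand; the TES is the opposite
    extremity.  One TSS per gene: multi-transcript annotations collapse to
    the gene-level extremal coordinates.
    """

    gene_id: str
    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            object.__setattr__(self, "exons", (self.interval,))
        else:
            object.__setattr__(self, "exons", _merge_intervals(self.exons))
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon {ex} outside gene interval")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class CpGIsland:
    """A CpG island: an unstranded interval with an identifier."""

    cgi_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class CgiGeneUnit:
    """A CGI paired with a gene whose promoter it overlaps by >= 1 bp."""

    cgi_id: str
    gene_id: str
    promoter: GenomicInterval
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("overlap_bp must be >= 1")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from an Ensembl-dialect GTF file.

    Uses ``gene`` and ``exon`` features; exons are merged per gene and GTF
    1-based closed coordinates are converted to 0-based half-open.  A gene
    without a ``gene`` feature takes the span of its exons; a gene with no
    exons uses its own interval as a single exon (with a warning).

    Raises
    ------
    ValueError
        On a malformed line, naming the line number.
    """
    gene_iv: dict[str, GenomicInterval] = {}
    gene_name: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: malformed GTF line {lineno}: strand {strand!r}")
            attributes = _parse_gtf_attributes(attrs)
            gid = attributes.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if gid not in exons and gid not in gene_iv:
                order.append(gid)
            if feature == "gene":
                gene_iv[gid] = iv
                if "gene_name" in attributes:
                    gene_name[gid] = attributes["gene_name"]
            else:
                exons.setdefault(gid, []).append(iv)

    genes: list[GeneModel] = []
    for gid in order:
        ex = exons.get(gid, [])
        if gid in gene_iv:
            iv = gene_iv[gid]
        else:
            chrom = ex[0].chrom
            strand = ex[0].strand
            iv = GenomicInterval(chrom, min(e.start for e in ex), max(e.end for e in ex), strand)
        if not ex:
            warnings.warn(f"gene {gid} has no exon features; using gene interval as single exon")
            ex = [iv]
        genes.append(GeneModel(gene_id=gid, name=gene_name.get(gid, gid), interval=iv, exons=tuple(ex)))
    return genes


def load_cgis(path: str | Path) -> list[CpGIsland]:
    """Read CpG islands from a BED file (>= 3 columns, UCSC cpgIslandExt style).

    Column 4, when present, is used as the CGI id; otherwise sequential ids
    are assigned in file order.
    """
    cgis: list[CpGIsland] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] else f"CGI_{len(cgis):05d}"
            cgis.append(CpGIsland(name, GenomicInterval(chrom, start, end)))
    return cgis


def derive_promoter(gene: GeneModel, upstream_bp: int = 2000) -> GenomicInterval:
    """The promoter: ``upstream_bp`` immediately upstream of the TSS.

    The promoter excludes the TSS base itself and is truncated at
    chromosome position 0.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be > 0")
    if gene.strand == "+":
        start = max(0, gene.tss - upstream_bp)
        end = gene.tss
    else:
        start = gene.tss + 1
        end = gene.tss + 1 + upstream_bp
    return GenomicInterval(gene.interval.chrom, start, end, gene.strand)


def derive_shores(
    cgi: CpGIsland, flank_bp: int = 2000
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """The CGI shores: ``flank_bp`` up- and downstream flanks of the CGI.

    Shores exclude the CGI itself; the left shore is truncated at position 0.
    An empty (zero-length) shore is returned as ``None``.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    iv = cgi.interval
    left_start = max(0, iv.start - flank_bp)
    left = GenomicInterval(iv.chrom, left_start, iv.start) if left_start < iv.start else None
    right = GenomicInterval(iv.chrom, iv.end, iv.end + flank_bp) if flank_bp > 0 else None
    return left, right


def map_cgis_to_genes(
    cgis: Iterable[CpGIsland],
    genes: Iterable[GeneModel],
    upstream_bp: int = 2000,
    min_overlap_bp: int = 1,
) -> list[CgiGeneUnit]:
    """Pair every CGI with every gene whose promoter it overlaps.

    One :class:`CgiGeneUnit` per (CGI, gene) pair with an intersection of at
    least ``min_overlap_bp``; a CGI overlapping k promoters yields k units.
    The result is sorted by (chrom, CGI start, gene_id).
    """
    promoters: dict[str, IntervalTree] = {}
    for gene in genes:
        prom = derive_promoter(gene, upstream_bp)
        promoters.setdefault(prom.chrom, IntervalTree())[prom.start:prom.end] = (gene.gene_id, prom)

    units: list[tuple[str, int, str, CgiGeneUnit]] = []
    for cgi in cgis:
        tree = promoters.get(cgi.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(cgi.interval.start, cgi.interval.end):
            gene_id, prom = hit.data
            overlap = cgi.interval.intersect_len(prom)
            if overlap >= min_overlap_bp:
                units.append(
                    (cgi.interval.chrom, cgi.interval.start, gene_id,
                     CgiGeneUnit(cgi.cgi_id, gene_id, prom, overlap))
                )
    units.sort(key=lambda t: t[:3])
    return [u for *_key, u in units]


class FeatureIndex:
    """Interval index over promoters, gene bodies, CGIs and shores.

    Built once from an annotation, then queried per site; labels are
    non-exclusive (a site may be both ``promoter`` and ``CGI``);
    ``intergenic`` applies iff no other label does.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        cgis: Iterable[CpGIsland],
        upstream_bp: int = 2000,
        shore_bp: int = 2000,
    ) -> None:
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        self._chroms: set[str] = set()

        def add(label: str, iv: GenomicInterval | None) -> None:
            if iv is None:
                return
            self._chroms.add(iv.chrom)
            self._trees.setdefault(label, {}).setdefault(iv.chrom, IntervalTree())[
                iv.start:iv.end
            ] = True

        for gene in genes:
            add("promoter", derive_promoter(gene, upstream_bp))
            add("gene_body", gene.interval)
        for cgi in cgis:
            add("CGI", cgi.interval)
            left, right = derive_shores(cgi, shore_bp)
            add("shore", left)
            add("shore", right)

    def classify(self, chrom: str, pos: int) -> set[str]:
        if chrom not in self._chroms:
            warnings.warn(f"unknown chromosome {chrom!r}; classifying as intergenic")
            return {"intergenic"}
        labels = {
            label
            for label, per_chrom in self._trees.items()
            if chrom in per_chrom and per_chrom[chrom].overlaps(pos)
        }
        return labels or {"intergenic"}


def classify_site_feature(
    chrom: str,
    pos: int,
    genes: Iterable[GeneModel],
    cgis: Iterable[CpGIsland],
    upstream_bp: int = 2000,
    shore_bp: int = 2000,
) -> set[str]:
    """Classify one position; for many sites build a :class:`FeatureIndex` once."""
    return FeatureIndex(genes, cgis, upstream_bp, shore_bp).classify(chrom, pos)


def write_bed6(
    intervals: Iterable[GenomicInterval],
    names: Iterable[str],
    path: str | Path,
    scores: Iterable[float] | None = None,
) -> None:
    """Write intervals as BED6 (0-based half-open)."""
    intervals = list(intervals)
    names = list(names)
    scores_l = list(scores) if scores is not None else [0.0] * len(intervals)
    if not (len(intervals) == len(names) == len(scores_l)):
        raise ValueError("intervals, names and scores must have equal length")
    with open(path, "w") as fh:
        for iv, name, score in zip(intervals, names, scores_l):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def write_gene_models_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal Ensembl-dialect GTF (gene + exon lines)."""
    with open(path, "w") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.name}";'
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tmethlink\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in gene.exons:
                fh.write(
                    f"{ex.chrom}\tmethlink\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def write_cgis_bed(cgis: Iterable[CpGIsland], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cgi in cgis:
            iv = cgi.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cgi.cgi_id}\n")
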