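"""Genomic interval engine: overlap queries, feature annotation, enhancer calling.

All coordinates are 0-based, half-open (BED-native): an interval covers
positions ``start .. end-1`` and two intervals overlap iff
``min(end1, end2) - max(start1, start2) >= 1``. The same convention is used
by every module in this package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1000  # bp upstream of the TSS (transcription direction)
PROMOTER_DOWNSTREAM = 100  # bp downstream of the TSS


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional BED6 metadata."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene: identifier, strand, TSS, genomic span and optional exons.

    The TSS is the 0-based position of the first transcribed base; for a
    minus-strand gene it sits at the right-hand edge of the span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.start <= self.tss <= self.end):
            raise ValueError(
                f"TSS {self.tss} outside span [{self.start}, {self.end}] "
                f"for {self.gene_id}"
            )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.gene_id, strand=self.strand)

    def promoter_window(self) -> GenomicInterval:
        """Strand-aware promoter window TSS-1000 .. TSS+100.

        Plus strand: ``[tss - 1000, tss + 100)``. Minus strand: the window is
        mirrored around the TSS so it still extends 1000 bp upstream and
        100 bp downstream in the direction of transcription:
        ``[tss - 99, tss + 1001)``. Clipped at 0.
        """
        if self.strand == "+":
            lo, hi = self.tss - PROMOTER_UPSTREAM, self.tss + PROMOTER_DOWNSTREAM
        else:
            lo = self.tss - PROMOTER_DOWNSTREAM + 1
            hi = self.tss + PROMOTER_UPSTREAM + 1
        return GenomicInterval(self.chrom, max(0, lo), hi,
                               name=self.gene_id, strand=self.strand)


FEATURE_CLASSES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class AnnotatedRegion:
    region: GenomicInterval
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


def build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index intervals by chromosome for fast stabbing/overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_query(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All (query, subject) pairs sharing >= ``min_bp`` on the same chromosome.

    Strand is ignored. Empty inputs yield an empty list. The returned pair
    set is symmetric in content under swapping query and subject.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = build_trees(subject)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for q in query:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            s = hit.data
            if q.overlap_bp(s) >= min_bp:
                pairs.append((q, s))
    return pairs


def annotate_region(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    _trees: dict[str, dict[str, IntervalTree]] | None = None,
) -> AnnotatedRegion:
    """Assign one genomic feature class to a region by its midpoint.

    Precedence: promoter > exon > intron > intergenic. The promoter window
    is the strand-aware TSS-1000..TSS+100; exon/intron use the exon model
    attached to each gene. A region on a chromosome with no annotated gene
    is intergenic (with a warning).
    """
    trees = _trees if _trees is not None else _annotation_trees(genes)
    if region.chrom not in trees["span"] and region.chrom not in trees["promoter"]:
        warnings.warn(f"region on unannotated chrom {region.chrom!r}: intergenic",
                      stacklevel=2)
        return AnnotatedRegion(region, "intergenic")
    mid = region.midpoint
    for cls in ("promoter", "exon", "intron"):
        tree = trees[cls].get(region.chrom)
        if tree is not None and tree.overlaps_point(mid):
            return AnnotatedRegion(region, cls)
    return AnnotatedRegion(region, "intergenic")


def annotate_regions(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[AnnotatedRegion]:
    """Annotate many regions against one gene model (shared index)."""
    trees = _annotation_trees(genes)
    return [annotate_region(r, genes, _trees=trees) for r in regions]


def annotation_counts(annotated: Sequence[AnnotatedRegion]) -> dict[str, int]:
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for a in annotated:
        counts[a.feature_class] += 1
    return counts


def _annotation_trees(genes: Sequence[GeneModel]) -> dict[str, dict[str, IntervalTree]]:
    promoter: dict[str, IntervalTree] = {}
    exon: dict[str, IntervalTree] = {}
    span: dict[str, IntervalTree] = {}
    for g in genes:
        w = g.promoter_window()
        promoter.setdefault(g.chrom, IntervalTree()).addi(w.start, w.end)
        span.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        for (s, e) in g.exons:
            exon.setdefault(g.chrom, IntervalTree()).addi(s, e)
    return {"promoter": promoter, "exon": exon, "span": span, "intron": span}


def call_daes(
    dar_intervals: Sequence[GenomicInterval],
    k4me1: Sequence[GenomicInterval],
    k27ac: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Differentially accessible putative enhancers (DAEs).

    A DAR is a DAE iff it overlaps (>= 1 bp) at least one H3K4me1 peak AND
    at least one H3K27ac peak — the co-mark filter that defines putative
    enhancers. Order and metadata (including the accessibility direction
    carried in ``name``/``score``) are preserved. The result is always a
    subset of the input DARs.
    """
    k4_trees = build_trees(k4me1)
    k27_trees = build_trees(k27ac)
    out = []
    for dar in dar_intervals:
        t4 = k4_trees.get(dar.chrom)
        t27 = k27_trees.get(dar.chrom)
        if t4 is None or t27 is None:
            continue
        if t4.overlap(dar.start, dar.end) and t27.overlap(dar.start, dar.end):
            out.append(dar)
    return out
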