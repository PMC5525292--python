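"""Genomic coordinate primitives: intervals, promoters, and an overlap index.

All coordinates are 0-based half-open ([start, end)), the native convention of
the BED/BEDPE family. A CpG probe interrogates a single site and is treated as
the 1-bp interval [pos, pos+1) in every overlap test. Promoters are derived
strand-aware around the TSS: "upstream" always means 5' of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """A gene reduced to its TSS; one TSS per gene_id is assumed."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True, order=True)
class CpGProbe:
    """A methylation-array probe interrogating a single CpG site."""

    probe_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)


def promoter_of(
    gene: GeneAnnotation, upstream: int = 2000, downstream: int = 500
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at position 0.

    On the + strand the window is [tss - upstream, tss + downstream); on the
    - strand it mirrors to [tss - downstream, tss + upstream).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(0, start)
    if end <= start:  # zero-width request; keep a 1-bp token at the TSS
        end = start + 1
    return GenomicInterval(gene.chrom, start, end)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chrom."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


class IntervalIndex:
    """Chromosome-partitioned interval tree over (interval, payload) items.

    Queries return exactly what a brute-force all-pairs overlap scan returns,
    sorted by (interval, payload-insertion order) for determinism.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[tuple[GenomicInterval, object]] = []

    @classmethod
    def build(
        cls, items: Iterable[GenomicInterval | tuple[GenomicInterval, object]]
    ) -> "IntervalIndex":
        index = cls()
        for item in items:
            if isinstance(item, GenomicInterval):
                interval, payload = item, None
            else:
                interval, payload = item
            idx = len(index._items)
            index._items.append((interval, payload))
            tree = index._trees.setdefault(interval.chrom, IntervalTree())
            tree.addi(interval.start, interval.end, idx)
        return index

    def __len__(self) -> int:
        return len(self._items)

    def query(
        self, probe: GenomicInterval | tuple[str, int]
    ) -> list[tuple[GenomicInterval, object]]:
        """All stored items overlapping `probe` (interval or (chrom, pos) point)."""
        if isinstance(probe, tuple):
            chrom, pos = probe
            probe = GenomicInterval(chrom, pos, pos + 1)
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        hits = sorted(hit.data for hit in tree.overlap(probe.start, probe.end))
        return [self._items[i] for i in hits]

    def query_intervals(
        self, probe: GenomicInterval | tuple[str, int]
    ) -> list[GenomicInterval]:
        return [interval for interval, _ in self.query(probe)]


def build_index(
    intervals: Sequence[GenomicInterval | tuple[GenomicInterval, object]],
) -> IntervalIndex:
    """Functional alias for :meth:`IntervalIndex.build`."""
    return IntervalIndex.build(intervals)
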