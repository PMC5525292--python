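"""Paired-end-tag (ChIA-PET) interactions and distal CpG -> target-gene pairing.

A PET evidences a physical chromatin loop between two anchors. A gene whose
promoter overlaps one anchor is a *target gene* of that loop; any CpG probe
overlapping the *opposite* anchor is a *distal CpG* candidate regulator of it.
Pairing is strictly "opposite ends": a probe and a promoter co-located on the
same anchor create no pair by themselves, but a probe sitting inside one
promoter may still pair with the gene anchored at the other end (the
promoter-promoter loop situation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import (
    CpGProbe,
    GeneAnnotation,
    GenomicInterval,
    IntervalIndex,
    promoter_of,
)

log = logging.getLogger(__name__)


class BedpeParseError(ValueError):
    """A malformed BEDPE record, carrying the 1-based line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class ChromatinInteraction:
    """One PET: two anchors, optionally with a read-support count."""

    pet_id: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    support: int = 1

    @property
    def inter_chromosomal(self) -> bool:
        return self.anchor1.chrom != self.anchor2.chrom

    def anchor(self, slot: int) -> GenomicInterval:
        if slot == 1:
            return self.anchor1
        if slot == 2:
            return self.anchor2
        raise ValueError("anchor slot must be 1 or 2")


@dataclass
class CpGGenePair:
    """A candidate long-range regulation edge with its filter evidence.

    Evidence slots are attached by the downstream filter stages; a freshly
    paired edge carries only its loop witnesses (pet_ids).
    """

    probe_id: str
    gene_id: str
    pet_ids: tuple[str, ...]
    delta_beta: float | None = None
    logrank_p: float | None = None
    pearson_r: float | None = None
    deg_flag: bool | None = None
    extras: dict = field(default_factory=dict)

    def key(self) -> tuple[str, str]:
        return (self.probe_id, self.gene_id)


def read_bedpe(path, on_malformed: str = "error") -> list[ChromatinInteraction]:
    """Parse a >=6-column BEDPE file into interactions.

    Columns: chrom1 start1 end1 chrom2 start2 end2 [name [score ...]].
    Missing names become ``PET<lineno>``; an integer score column is read as
    PET support. ``on_malformed`` is ``"error"`` (default) or ``"skip"``
    (log a warning with the line number and continue).
    """
    if on_malformed not in ("error", "skip"):
        raise ValueError("on_malformed must be 'error' or 'skip'")
    interactions: list[ChromatinInteraction] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 6:
                    raise ValueError(
                        f"expected >= 6 tab-separated columns, got {len(fields)}"
                    )
                chrom1, chrom2 = fields[0], fields[3]
                start1, end1 = int(fields[1]), int(fields[2])
                start2, end2 = int(fields[4]), int(fields[5])
                name = fields[6] if len(fields) > 6 and fields[6] not in ("", ".") else f"PET{lineno}"
                support = 1
                if len(fields) > 7:
                    try:
                        support = max(1, int(float(fields[7])))
                    except ValueError:
                        support = 1
                interaction = ChromatinInteraction(
                    pet_id=name,
                    anchor1=GenomicInterval(chrom1, start1, end1),
                    anchor2=GenomicInterval(chrom2, start2, end2),
                    support=support,
                )
            except ValueError as exc:
                if on_malformed == "skip":
                    log.warning("skipping malformed BEDPE line %d: %s", lineno, exc)
                    continue
                raise BedpeParseError(lineno, str(exc)) from exc
            interactions.append(interaction)
    return interactions


def _promoter_index(
    genes: Sequence[GeneAnnotation], upstream: int, downstream: int
) -> IntervalIndex:
    return IntervalIndex.build(
        (promoter_of(g, upstream, downstream), g.gene_id) for g in genes
    )


def anchor_promoter_hits(
    interactions: Iterable[ChromatinInteraction],
    genes: Sequence[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 500,
) -> dict[tuple[str, int], frozenset[str]]:
    """For each (pet_id, anchor slot), the genes whose promoter overlaps it."""
    promoters = _promoter_index(genes, upstream, downstream)
    hits: dict[tuple[str, int], frozenset[str]] = {}
    for pet in interactions:
        for slot in (1, 2):
            gene_ids = frozenset(
                gid for _, gid in promoters.query(pet.anchor(slot))
            )
            hits[(pet.pet_id, slot)] = gene_ids
    return hits


def pair_cpgs_to_targets(
    interactions: Sequence[ChromatinInteraction],
    probes: Sequence[CpGProbe],
    genes: Sequence[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 500,
    min_support: int = 1,
    drop_inter_chromosomal: bool = False,
) -> list[CpGGenePair]:
    """Resolve PETs into distal CpG -> target-gene candidate pairs.

    For every PET and each anchor slot whose *opposite* anchor overlaps at
    least one promoter, every probe overlapping that slot pairs with each such
    target gene. Pairs are deduplicated over PETs, accumulating supporting
    pet_ids, and returned sorted by (probe_id, gene_id).
    """
    promoters = _promoter_index(genes, upstream, downstream)
    probe_index = IntervalIndex.build((p.interval(), p.probe_id) for p in probes)

    witnesses: dict[tuple[str, str], set[str]] = {}
    for pet in interactions:
        if pet.support < min_support:
            continue
        if drop_inter_chromosomal and pet.inter_chromosomal:
            continue
        anchor_genes = {
            slot: {gid for _, gid in promoters.query(pet.anchor(slot))}
            for slot in (1, 2)
        }
        for slot, opposite in ((1, 2), (2, 1)):
            targets = anchor_genes[opposite]
            if not targets:
                continue
            probe_ids = [pid for _, pid in probe_index.query(pet.anchor(slot))]
            for probe_id in probe_ids:
                for gene_id in targets:
                    witnesses.setdefault((probe_id, gene_id), set()).add(pet.pet_id)

    return [
        CpGGenePair(probe_id=pid, gene_id=gid, pet_ids=tuple(sorted(pets)))
        for (pid, gid), pets in sorted(witnesses.items())
    ]
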