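"""BEDPE parsing and the opposite-end CpG -> target-gene pairing rule."""

import numpy as np
import pytest

from loopmark.intervals import CpGProbe, GeneAnnotation, GenomicInterval, overlaps, promoter_of
from loopmark.pairing import (
    BedpeParseError,
    ChromatinInteraction,
    anchor_promoter_hits,
    pair_cpgs_to_targets,
    read_bedpe,
)


def _pet(pet_id, a1, a2):
    return ChromatinInteraction(pet_id, GenomicInterval("chr1", *a1), GenomicInterval("chr1", *a2))


def _random_instance(rng, n_probes=100, n_genes=50, n_pets=30, span=500_000):
    probes = [
        CpGProbe(f"cg{i}", "chr1", int(p))
        for i, p in enumerate(rng.integers(0, span, n_probes))
    ]
    genes = [
        GeneAnnotation(f"G{i}", "chr1", str(s), int(t))
        for i, (t, s) in enumerate(
            zip(rng.integers(5000, span, n_genes), rng.choice(["+", "-"], n_genes))
        )
    ]
    pets = []
    for i in range(n_pets):
        s1, s2 = rng.integers(0, span, 2)
        pets.append(_pet(f"PET{i}", (int(s1), int(s1) + 3000), (int(s2), int(s2) + 3000)))
    return probes, genes, pets


def triple_loop_pairing_oracle(pets, probes, genes, up=2000, down=500):
    """Exhaustive (PET x probe x gene) enumeration of the opposite-end rule."""
    promoters = {g.gene_id: promoter_of(g, up, down) for g in genes}
    witnessed = {}
    for pet in pets:
        for slot, opposite in ((pet.anchor1, pet.anchor2), (pet.anchor2, pet.anchor1)):
            for probe in probes:
                if not overlaps(probe.interval(), slot):
                    continue
                for gene in genes:
                    if overlaps(promoters[gene.gene_id], opposite):
                        witnessed.setdefault((probe.probe_id, gene.gene_id), set()).add(pet.pet_id)
    return witnessed


class TestReadBedpe:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bedpe"
        path.write_text("")
        assert read_bedpe(path) == []

    def test_identity_parse(self, tmp_path):
        path = tmp_path / "three.bedpe"
        path.write_text(
            "chr1\t100\t200\tchr1\t5000\t6000\tA\t3\n"
            "chr1\t300\t400\tchr2\t10\t20\n"
            "chrX\t0\t50\tchrX\t60\t90\tC\n"
        )
        pets = read_bedpe(path)
        assert len(pets) == 3
        assert pets[0].pet_id == "A" and pets[0].support == 3
        assert pets[0].anchor1 == GenomicInterval("chr1", 100, 200)
        assert pets[1].pet_id == "PET2"  # auto-named from the line number
        assert pets[1].inter_chromosomal
        assert pets[2].anchor2 == GenomicInterval("chrX", 60, 90)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t100\t200\tchr1\t5000\t6000\nchr1\t500\t400\tchr1\t1\t2\n")
        with pytest.raises(BedpeParseError, match="line 2"):
            read_bedpe(path)
        assert len(read_bedpe(path, on_malformed="skip")) == 1

    def test_unreadable_file_fatal(self, tmp_path):
        with pytest.raises(OSError):
            read_bedpe(tmp_path / "does_not_exist.bedpe")


class TestAnchorPromoterHits:
    def test_disjoint_and_single(self):
        genes = [GeneAnnotation("G1", "chr1", "+", 52_000)]
        pet = _pet("P1", (1000, 2000), (49_000, 53_000))
        hits = anchor_promoter_hits([pet], genes)
        assert hits[("P1", 1)] == frozenset()
        assert hits[("P1", 2)] == frozenset({"G1"})

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        _, genes, pets = _random_instance(rng, n_genes=200, n_pets=100)
        hits = anchor_promoter_hits(pets, genes)
        promoters = {g.gene_id: promoter_of(g) for g in genes}
        for pet in pets:
            for slot in (1, 2):
                expected = {
                    gid for gid, prom in promoters.items()
                    if overlaps(prom, pet.anchor(slot))
                }
                assert hits[(pet.pet_id, slot)] == expected


class TestPairCpgsToTargets:
    def test_direct_rule(self):
        # probe in anchor A, gene promoter inside anchor B -> one pair
        probes = [CpGProbe("cg1", "chr1", 1500)]
        genes = [GeneAnnotation("G", "chr1", "+", 52_000)]  # promoter [50000, 52500)
        pet = _pet("P1", (1000, 2000), (49_500, 53_000))
        pairs = pair_cpgs_to_targets([pet], probes, genes)
        assert [(p.probe_id, p.gene_id, p.pet_ids) for p in pairs] == [("cg1", "G", ("P1",))]

    def test_promoter_promoter_pet_pairs_both_ways(self):
        # two promoters looped to each other; CpGs on each promoter pair with
        # the gene anchored at the opposite end (the HOXA9/HOXA10 situation)
        gene_a = GeneAnnotation("GA", "chr1", "+", 12_000)   # promoter [10000, 12500)
        gene_b = GeneAnnotation("GB", "chr1", "+", 52_000)   # promoter [50000, 52500)
        probes = [
            CpGProbe("a1", "chr1", 10_100), CpGProbe("a2", "chr1", 10_200),
            CpGProbe("a3", "chr1", 10_300), CpGProbe("a4", "chr1", 10_400),
            CpGProbe("b1", "chr1", 50_100), CpGProbe("b2", "chr1", 50_200),
        ]
        pet = _pet("P1", (10_000, 12_500), (50_000, 52_500))
        pairs = pair_cpgs_to_targets([pet], probes, [gene_a, gene_b])
        keys = {(p.probe_id, p.gene_id) for p in pairs}
        # anchor-A probes target GB (and GA, since GA's promoter also overlaps
        # the opposite-promoter-anchored end is false here: GA promoter is on
        # anchor 1 only) and vice versa
        assert {("a1", "GB"), ("a2", "GB"), ("a3", "GB"), ("a4", "GB")} <= keys
        assert {("b1", "GA"), ("b2", "GA")} <= keys
        # same-anchor co-location alone creates no pair
        assert ("a1", "GA") not in keys
        assert ("b1", "GB") not in keys

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        probes, genes, pets = _random_instance(rng, n_probes=500, n_genes=200, n_pets=100)
        pairs = pair_cpgs_to_targets(pets, probes, genes)
        oracle = triple_loop_pairing_oracle(pets, probes, genes)
        got = {p.key(): set(p.pet_ids) for p in pairs}
        assert got == oracle

    def test_witness_invariant(self, seed=3):
        rng = np.random.default_rng(seed)
        probes, genes, pets = _random_instance(rng)
        promoters = {g.gene_id: promoter_of(g) for g in genes}
        probe_by_id = {p.probe_id: p for p in probes}
        pet_by_id = {p.pet_id: p for p in pets}
        for pair in pair_cpgs_to_targets(pets, probes, genes):
            for pet_id in pair.pet_ids:
                pet = pet_by_id[pet_id]
                probe_iv = probe_by_id[pair.probe_id].interval()
                prom = promoters[pair.gene_id]
                assert (
                    overlaps(probe_iv, pet.anchor1) and overlaps(prom, pet.anchor2)
                ) or (
                    overlaps(probe_iv, pet.anchor2) and overlaps(prom, pet.anchor1)
                )

    def test_monotone_in_interactions(self):
        rng = np.random.default_rng(4)
        probes, genes, pets = _random_instance(rng)
        small = {p.key() for p in pair_cpgs_to_targets(pets[:15], probes, genes)}
        large = {p.key() for p in pair_cpgs_to_targets(pets, probes, genes)}
        assert small <= large

    def test_anchor_swap_symmetry(self):
        rng = np.random.default_rng(5)
        probes, genes, pets = _random_instance(rng)
        swapped = [
            ChromatinInteraction(p.pet_id, p.anchor2, p.anchor1, p.support) for p in pets
        ]
        original = {p.key(): p.pet_ids for p in pair_cpgs_to_targets(pets, probes, genes)}
        mirrored = {p.key(): p.pet_ids for p in pair_cpgs_to_targets(swapped, probes, genes)}
        assert original == mirrored

    def test_sorted_and_deduplicated(self):
        probes = [CpGProbe("cg1", "chr1", 1500)]
        genes = [GeneAnnotation("G", "chr1", "+", 52_000)]
        pets = [
            _pet("P2", (1000, 2000), (49_500, 53_000)),
            _pet("P1", (1400, 2400), (49_500, 53_000)),
        ]
        pairs = pair_cpgs_to_targets(pets, probes, genes)
        assert len(pairs) == 1
        assert pairs[0].pet_ids == ("P1", "P2")
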