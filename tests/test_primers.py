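"""Primer design and in-silico PCR: constraints, amplicons, specificity."""

import pytest
from conftest import random_dna

from raretaxa.genomes import GeneRecord, GenomeSet, reverse_complement
from raretaxa.primers import (
    PrimerConstraints, PrimerPair, design_primers, gc_percent,
    insilico_pcr, melting_temperature, specificity_check,
)


class TestMeltingTemperature:
    @pytest.mark.parametrize("oligo,tm", [
        ("AAAA", 8.0),
        ("GGGG", 16.0),
        ("ATATATATAT" + "GCGCGCGCGC", 60.0),  # 10 AT + 10 GC
    ])
    def test_wallace_rule(self, oligo, tm):
        assert melting_temperature(oligo) == tm

    def test_rejects_degenerate_bases(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGN")


def _constraint_ok(pair: PrimerPair, c: PrimerConstraints) -> bool:
    """Independent re-validation of a designed pair against the constraints."""
    for oligo in (pair.forward, pair.reverse):
        gc = 100.0 * (oligo.count("G") + oligo.count("C")) / len(oligo)
        tm = 2.0 * (len(oligo) - oligo.count("G") - oligo.count("C")) \
            + 4.0 * (oligo.count("G") + oligo.count("C"))
        if not (c.length_min <= len(oligo) <= c.length_max):
            return False
        if not (c.gc_min <= gc <= c.gc_max and c.tm_min <= tm <= c.tm_max):
            return False
    return (
        c.product_min <= pair.expected_product_length <= c.product_max
        and abs(pair.tm_forward - pair.tm_reverse) <= c.max_tm_diff
    )


class TestDesignPrimers:
    def test_template_shorter_than_product_is_infeasible(self, rng):
        assert design_primers(random_dna(rng, 60)) == []

    def test_homopolymer_fails_gc_constraint(self):
        assert design_primers("A" * 500) == []

    def test_every_emitted_pair_revalidates(self, rng):
        template = random_dna(rng, 500)
        constraints = PrimerConstraints()
        pairs = design_primers(template, constraints, max_pairs=None)
        assert pairs, "expected feasible pairs on a 500 bp random template"
        assert all(_constraint_ok(p, constraints) for p in pairs)

    def test_deterministic_ranking(self, rng):
        template = random_dna(rng, 400)
        first = design_primers(template)
        second = design_primers(template)
        assert [(p.forward, p.reverse, p.penalty) for p in first] == \
               [(p.forward, p.reverse, p.penalty) for p in second]

    def test_primers_anneal_to_their_template(self, rng):
        template = random_dna(rng, 500)
        pairs = design_primers(template, max_pairs=3)
        gs = GenomeSet(genomes={"g": [GeneRecord("t", template)]})
        for pair in pairs:
            hits = insilico_pcr(pair, gs, max_mismatches_per_primer=0)
            assert any(h.product_length == pair.expected_product_length for h in hits)


def _pair(forward, reverse):
    return PrimerPair(
        name="p", forward=forward, reverse=reverse,
        tm_forward=0.0, tm_reverse=0.0, gc_forward=0.0, gc_reverse=0.0,
        expected_product_length=len(forward) + len(reverse),
    )


class TestInsilicoPcr:
    def _constructed(self, rng):
        fwd = random_dna(rng, 20)
        rev = random_dna(rng, 20)
        insert = random_dna(rng, 100)
        template = fwd + insert + reverse_complement(rev)
        return _pair(fwd, rev), template

    def test_constructed_template_single_hit(self, rng):
        pair, template = self._constructed(rng)
        gs = GenomeSet(genomes={"g": [GeneRecord("t", template)]})
        hits = insilico_pcr(pair, gs)
        assert len(hits) == 1
        (hit,) = hits
        assert hit.product_length == len(pair.forward) + 100 + len(pair.reverse)
        assert hit.start == 0 and hit.end == len(template)
        assert hit.strand == "+"

    def test_absent_primers_no_hits(self, rng):
        pair = _pair("A" * 20, "C" * 20)
        gs = GenomeSet(genomes={"g": [GeneRecord("t", random_dna(rng, 300))]})
        assert insilico_pcr(pair, gs) == []

    def test_strand_symmetry(self, rng):
        pair, template = self._constructed(rng)
        fwd_gs = GenomeSet(genomes={"g": [GeneRecord("t", template)]})
        rc_gs = GenomeSet(genomes={"g": [GeneRecord("t", reverse_complement(template))]})
        fwd_hits = insilico_pcr(pair, fwd_gs)
        rc_hits = insilico_pcr(pair, rc_gs)
        assert len(fwd_hits) == len(rc_hits) == 1
        assert rc_hits[0].strand == "-"
        assert rc_hits[0].product_length == fwd_hits[0].product_length

    def test_exact_mode_binding_sites_equal_primers(self, rng):
        pair, template = self._constructed(rng)
        gs = GenomeSet(genomes={"g": [GeneRecord("t", template)]})
        (hit,) = insilico_pcr(pair, gs, max_mismatches_per_primer=0)
        assert template[hit.start:hit.start + len(pair.forward)] == pair.forward
        assert template[hit.end - len(pair.reverse):hit.end] == \
            reverse_complement(pair.reverse)

    def test_record_order_invariance(self, rng):
        pair, template = self._constructed(rng)
        other = random_dna(rng, 200)
        a = GenomeSet(genomes={"g": [GeneRecord("t", template), GeneRecord("u", other)]})
        b = GenomeSet(genomes={"g": [GeneRecord("u", other), GeneRecord("t", template)]})
        assert len(insilico_pcr(pair, a)) == len(insilico_pcr(pair, b))

    def test_mismatch_allowance_and_3prime_guard(self, rng):
        pair, template = self._constructed(rng)
        # mutate one internal base of the forward binding site
        mutated = list(template)
        mutated[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[5]]
        gs = GenomeSet(genomes={"g": [GeneRecord("t", "".join(mutated))]})
        assert insilico_pcr(pair, gs, max_mismatches_per_primer=0) == []
        assert len(insilico_pcr(pair, gs, max_mismatches_per_primer=1)) == 1
        # mutate the 3'-terminal base instead: never tolerated
        mutated = list(template)
        i = len(pair.forward) - 1
        mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        gs = GenomeSet(genomes={"g": [GeneRecord("t", "".join(mutated))]})
        assert insilico_pcr(pair, gs, max_mismatches_per_primer=2) == []


@pytest.fixture(scope="module")
def discovered(small_pangenome):
    inclusion, exclusion, truth = small_pangenome
    ref_seqs = {r.gene_id: r.sequence for r in inclusion.genomes["ref"]}
    others = inclusion.subset([g for g in inclusion.genome_ids if g != "ref"])
    return ref_seqs, others, exclusion, truth


class TestSpecificity:
    def _best_pair(self, seq, gene_id):
        pairs = design_primers(seq, target_gene_id=gene_id, max_pairs=1)
        assert pairs, f"no feasible primers on {gene_id}"
        return pairs[0]

    def test_marker_gene_pair_is_specific(self, discovered):
        ref_seqs, others, exclusion, truth = discovered
        gid = sorted(truth.marker_gene_ids)[0]
        verdict = specificity_check(self._best_pair(ref_seqs[gid], gid), others, exclusion)
        assert verdict == "specific"

    def test_shared_gene_pair_is_non_specific(self, discovered):
        ref_seqs, others, exclusion, truth = discovered
        gid = sorted(truth.exclusion_shared_gene_ids)[0]
        verdict = specificity_check(self._best_pair(ref_seqs[gid], gid), others, exclusion)
        assert verdict == "non_specific"

    def test_reference_only_gene_is_non_universal(self, discovered):
        ref_seqs, others, exclusion, truth = discovered
        gid = sorted(set(ref_seqs) - truth.conserved_gene_ids)[0]
        verdict = specificity_check(self._best_pair(ref_seqs[gid], gid), others, exclusion)
        assert verdict == "non_universal"

    def test_empty_sets_rejected(self, discovered):
        ref_seqs, others, exclusion, truth = discovered
        gid = sorted(truth.marker_gene_ids)[0]
        pair = self._best_pair(ref_seqs[gid], gid)
        with pytest.raises(ValueError):
            specificity_check(pair, GenomeSet(genomes={}), exclusion)
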