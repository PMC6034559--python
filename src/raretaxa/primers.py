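"""Primer design and in-silico PCR specificity validation.

A minimal, fully deterministic primer designer stands in for Primer3:
it enumerates all primer windows on a marker-gene template, filters on
length, GC content, Wallace-rule melting temperature and product size,
and ranks surviving pairs by a simple additive penalty.  Designed pairs
are then validated by in-silico PCR: every binding site of the forward
primer on one strand paired with a downstream reverse-primer site on
the other strand, within a bounded product length, allowing a
configurable number of mismatches per primer but always requiring an
exact 3'-terminal match (polymerase extension is 3'-end sensitive).

The Wallace rule Tm = 2(A+T) + 4(G+C) is used throughout: closed-form,
exactly testable, adequate for the short oligos designed here.
Degenerate IUPAC bases are rejected rather than expanded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomes import GenomeSet, reverse_complement

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "AmpliconHit",
    "melting_temperature",
    "gc_percent",
    "design_primers",
    "insilico_pcr",
    "specificity_check",
]


def _check_acgt(oligo: str) -> str:
    if not oligo:
        raise ValueError("empty oligo")
    oligo = oligo.upper()
    bad = set(oligo) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in oligo: {sorted(bad)}")
    return oligo


def melting_temperature(oligo: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    oligo = _check_acgt(oligo)
    gc = oligo.count("G") + oligo.count("C")
    return 2.0 * (len(oligo) - gc) + 4.0 * gc


def gc_percent(oligo: str) -> float:
    oligo = _check_acgt(oligo)
    return 100.0 * (oligo.count("G") + oligo.count("C")) / len(oligo)


@dataclass(frozen=True)
class PrimerConstraints:
    """Designer constraints; defaults give conventional qPCR-sized oligos."""

    length_min: int = 18
    length_max: int = 25
    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 55.0
    tm_max: float = 62.0
    product_min: int = 80
    product_max: int = 300
    max_tm_diff: float = 3.0
    product_optimum: float = 150.0
    gc_optimum: float = 50.0


@dataclass
class PrimerPair:
    """Two oligos (both written 5'->3'; the reverse primer anneals to the minus strand)."""

    name: str
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    expected_product_length: int
    target_gene_id: str = ""
    penalty: float = 0.0

    def __post_init__(self) -> None:
        self.forward = _check_acgt(self.forward)
        self.reverse = _check_acgt(self.reverse)
        if self.expected_product_length < len(self.forward) + len(self.reverse):
            raise ValueError("product shorter than the two primers")


@dataclass
class AmpliconHit:
    """One predicted PCR product on a template (0-based, half-open coordinates)."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product_length: int = field(default=0)
    mismatches_forward: int = 0
    mismatches_reverse: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.product_length == 0:
            self.product_length = self.end - self.start
        if self.product_length != self.end - self.start:
            raise ValueError("product_length must equal end - start")


def _pair_penalty(tm_f, tm_r, gc_f, gc_r, product, c: PrimerConstraints) -> float:
    return (
        abs(tm_f - tm_r)
        + 0.5 * (abs(gc_f - c.gc_optimum) + abs(gc_r - c.gc_optimum))
        + abs(product - c.product_optimum)
    )


def design_primers(
    template: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    target_gene_id: str = "",
    max_pairs: int | None = 50,
) -> list[PrimerPair]:
    """Enumerate and rank all primer pairs satisfying the constraints.

    Infeasible constraints yield an empty list, not an error.  Ranking
    is by penalty = |dTm| + mean GC deviation from the optimum + product
    length deviation from the optimum, ties broken by (forward start,
    product length) so output is deterministic.
    """
    template = _check_acgt(template)
    c = constraints
    n = len(template)
    if n < c.product_min:
        return []

    def windows():
        for length in range(c.length_min, c.length_max + 1):
            for start in range(0, n - length + 1):
                oligo = template[start:start + length]
                gc = gc_percent(oligo)
                if not (c.gc_min <= gc <= c.gc_max):
                    continue
                tm = melting_temperature(oligo)
                if not (c.tm_min <= tm <= c.tm_max):
                    continue
                yield start, start + length, oligo, gc, tm

    forward = list(windows())
    if not forward:
        return []
    pairs = []
    for f_start, f_end, f_oligo, f_gc, f_tm in forward:
        for r_start, r_end, r_window, r_gc, r_tm in forward:
            product = r_end - f_start
            if r_start < f_end or not (c.product_min <= product <= c.product_max):
                continue
            if abs(f_tm - r_tm) > c.max_tm_diff:
                continue
            pairs.append((
                _pair_penalty(f_tm, r_tm, f_gc, r_gc, product, c),
                f_start, product, f_oligo, r_window, f_tm, r_tm, f_gc, r_gc,
            ))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    out = []
    for i, (penalty, f_start, product, f_oligo, r_window, f_tm, r_tm, f_gc, r_gc) in enumerate(pairs, 1):
        out.append(PrimerPair(
            name=f"{target_gene_id or 'pair'}_p{i:02d}",
            forward=f_oligo,
            reverse=reverse_complement(r_window),
            tm_forward=f_tm, tm_reverse=r_tm,
            gc_forward=f_gc, gc_reverse=r_gc,
            expected_product_length=product,
            target_gene_id=target_gene_id,
            penalty=penalty,
        ))
    return out


def _mismatch_positions(template: np.ndarray, primer: np.ndarray, max_mm: int,
                        exact_3prime_index: int) -> list[tuple[int, int]]:
    """All start positions where primer matches template with <= max_mm mismatches.

    exact_3prime_index is the primer-local index that must match exactly
    (len-1 for a forward primer, 0 for a plus-strand-written reverse site).
    """
    lp = len(primer)
    if len(template) < lp:
        return []
    win = np.lib.stride_tricks.sliding_window_view(template, lp)
    mm = (win != primer).sum(axis=1)
    ok = np.nonzero(mm <= max_mm)[0]
    hits = []
    for start in ok:
        if template[start + exact_3prime_index] != primer[exact_3prime_index]:
            continue
        hits.append((int(start), int(mm[start])))
    return hits


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_one_strand(pair: PrimerPair, template: str, max_mm: int, max_product: int):
    """Hits of the pair on the given plus-strand template text."""
    t = _enc(template)
    fwd = _enc(pair.forward)
    rev_site = _enc(reverse_complement(pair.reverse))  # reverse primer site on the plus strand
    f_hits = _mismatch_positions(t, fwd, max_mm, len(fwd) - 1)
    r_hits = _mismatch_positions(t, rev_site, max_mm, 0)
    for f_start, f_mm in f_hits:
        for r_start, r_mm in r_hits:
            end = r_start + len(rev_site)
            if r_start >= f_start + len(fwd) and end - f_start <= max_product:
                yield f_start, end, f_mm, r_mm


def insilico_pcr(
    pair: PrimerPair,
    genomes: GenomeSet,
    max_mismatches_per_primer: int = 0,
    max_product_length: int = 3000,
) -> list[AmpliconHit]:
    """Predict every amplicon of a primer pair across a genome set.

    Both template orientations are searched; minus-strand hits are
    reported in plus-strand coordinates.  The 3'-terminal base of each
    primer must match exactly regardless of the mismatch allowance.
    """
    hits = []
    for genome_id in sorted(genomes.genome_ids):
        for record in genomes.genomes[genome_id]:
            seq = record.sequence
            for f_start, end, f_mm, r_mm in _scan_one_strand(
                    pair, seq, max_mismatches_per_primer, max_product_length):
                hits.append(AmpliconHit(genome_id, record.gene_id, f_start, end, "+",
                                        mismatches_forward=f_mm, mismatches_reverse=r_mm))
            rc = reverse_complement(seq)
            for f_start, end, f_mm, r_mm in _scan_one_strand(
                    pair, rc, max_mismatches_per_primer, max_product_length):
                hits.append(AmpliconHit(genome_id, record.gene_id,
                                        len(seq) - end, len(seq) - f_start, "-",
                                        mismatches_forward=f_mm, mismatches_reverse=r_mm))
    hits.sort(key=lambda h: (h.genome_id, h.gene_id, h.start, h.end, h.strand))
    return hits


def specificity_check(
    pair: PrimerPair,
    inclusion: GenomeSet,
    exclusion: GenomeSet,
    max_mismatches_per_primer: int = 0,
    max_product_length: int = 3000,
) -> str:
    """Classify a pair as 'specific', 'non_specific' or 'non_universal'.

    specific: >= 1 amplicon in every inclusion genome and none in any
    exclusion genome.  Any exclusion amplicon wins over missing
    inclusion coverage (non_specific takes precedence).
    """
    if inclusion.n_genomes == 0 or exclusion.n_genomes == 0:
        raise ValueError("inclusion and exclusion genome sets must be non-empty")
    excl_hits = insilico_pcr(pair, exclusion, max_mismatches_per_primer, max_product_length)
    if excl_hits:
        return "non_specific"
    incl_hits = insilico_pcr(pair, inclusion, max_mismatches_per_primer, max_product_length)
    covered = {h.genome_id for h in incl_hits}
    if covered >= set(inclusion.genome_ids):
        return "specific"
    return "non_universal"
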