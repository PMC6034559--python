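"""Subtractive comparative-genomics marker discovery.

The procedure that yields clade-specific marker genes for a rare taxon:

1. *Conservation scan* — every gene of a reference genome is aligned
   against every genome of the inclusion clade; a gene is *conserved*
   when each inclusion genome carries a homolog above identity and
   coverage thresholds.
2. *Exclusion subtraction* — conserved genes with any above-threshold
   homolog in an exclusion clade (e.g. close relatives such as
   Clostridium spp. for SFB) are discarded.
3. *Ranking* — survivors are ordered by a conservation score (the mean
   over inclusion genomes of identity x coverage, both as fractions)
   and the top k become PCR marker candidates.

Homology cutoffs are deliberately explicit and overridable: inclusion
conservation defaults to identity >= 70% and coverage >= 70%, while the
exclusion scan uses the looser "some homology" cutoffs of 50%/50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import (
    DEFAULT_SEED_WORD_SIZE, HomologyHit, Scoring, best_hit, build_seed_index, kmer_set,
)
from .genomes import GenomeSet

__all__ = [
    "MarkerCandidate",
    "conservation_scan",
    "subtract_exclusion",
    "rank_and_select",
]

DEFAULT_IDENTITY_MIN = 70.0
DEFAULT_COVERAGE_MIN = 70.0
DEFAULT_IDENTITY_MIN_EXCL = 50.0
DEFAULT_COVERAGE_MIN_EXCL = 50.0
#: a threshold-passing hit must also score at least this fraction of the
#: query length.  The maximal local alignment between unrelated random
#: genes occasionally meanders through a long, gappy, low-scoring path
#: whose column identity and query coverage clear the percent cutoffs even
#: though the alignment score is barely above chance (tens of points for
#: 300 bp genes).  A genuine homolog at the threshold identities scores a
#: large fraction of the query length under +1/-1/-2 scoring, so the floor
#: separates the two regimes cleanly.
DEFAULT_MIN_SCORE_FRACTION = 0.2


def _passes(hit: Optional[HomologyHit], identity_min: float, coverage_min: float,
            query_length: int, min_score_frac: float) -> bool:
    return (
        hit is not None
        and hit.identity >= identity_min
        and hit.query_coverage >= coverage_min
        and hit.alignment_score >= min_score_frac * query_length
    )


@dataclass
class MarkerCandidate:
    """A reference gene with its cross-genome homology evidence."""

    gene_id: str
    best_hits: dict[str, Optional[HomologyHit]] = field(default_factory=dict)
    conserved: bool = False
    exclusion_hit: bool = False
    conservation_score: float = 0.0
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.conservation_score <= 1.0):
            raise ValueError("conservation_score must be in [0, 1]")

    @property
    def is_marker(self) -> bool:
        return self.conserved and not self.exclusion_hit


def _reference_genes(reference: GenomeSet):
    if reference.n_genomes == 0:
        raise ValueError("reference GenomeSet is empty")
    return [record for _, record in reference.iter_genes()]


def conservation_scan(
    reference: GenomeSet,
    inclusion: GenomeSet,
    identity_min: float = DEFAULT_IDENTITY_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    scoring: Scoring = Scoring(),
    min_score_frac: float = DEFAULT_MIN_SCORE_FRACTION,
    seed_word_size: Optional[int] = DEFAULT_SEED_WORD_SIZE,
) -> list[MarkerCandidate]:
    """Score every reference gene for conservation across the inclusion clade.

    A gene is conserved iff *every* inclusion genome has a best hit with
    identity >= identity_min and query_coverage >= coverage_min.  The
    conservation score averages identity x coverage (as fractions in
    [0,1]) over inclusion genomes, counting genomes without a hit as 0.
    """
    if inclusion.n_genomes == 0:
        raise ValueError("inclusion GenomeSet must contain at least one genome")
    indexes = (
        {g: build_seed_index(inclusion.genomes[g], seed_word_size)
         for g in inclusion.genome_ids}
        if seed_word_size is not None else {}
    )
    candidates = []
    for record in _reference_genes(reference):
        qk = kmer_set(record.sequence, seed_word_size) if seed_word_size is not None else None
        hits: dict[str, Optional[HomologyHit]] = {}
        score_sum = 0.0
        conserved = True
        for genome_id in inclusion.genome_ids:
            hit = best_hit(record.sequence, record.gene_id, genome_id,
                           inclusion.genomes[genome_id], scoring,
                           seed_word_size=seed_word_size, query_kmers=qk,
                           seed_index=indexes.get(genome_id))
            hits[genome_id] = hit
            if not _passes(hit, identity_min, coverage_min, len(record.sequence),
                           min_score_frac):
                conserved = False
            if hit is not None:
                score_sum += (hit.identity / 100.0) * (hit.query_coverage / 100.0)
        candidates.append(
            MarkerCandidate(
                gene_id=record.gene_id,
                best_hits=hits,
                conserved=conserved,
                conservation_score=score_sum / inclusion.n_genomes,
            )
        )
    return candidates


def subtract_exclusion(
    candidates: list[MarkerCandidate],
    exclusion: GenomeSet,
    identity_min: float = DEFAULT_IDENTITY_MIN_EXCL,
    coverage_min: float = DEFAULT_COVERAGE_MIN_EXCL,
    scoring: Scoring = Scoring(),
    reference: Optional[GenomeSet] = None,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRACTION,
    seed_word_size: Optional[int] = DEFAULT_SEED_WORD_SIZE,
) -> list[MarkerCandidate]:
    """Flag candidates with "some homology" to any exclusion genome.

    Requires the candidates' query sequences; pass the reference
    GenomeSet they were scanned from.  An empty exclusion set flags
    nothing (vacuous subtraction).  Returns the full annotated list;
    rank_and_select drops the flagged ones.
    """
    if exclusion.n_genomes == 0:
        return candidates
    if reference is None:
        raise ValueError("reference GenomeSet with candidate sequences is required")
    seq_by_id = {r.gene_id: r.sequence for _, r in reference.iter_genes()}
    indexes = (
        {g: build_seed_index(exclusion.genomes[g], seed_word_size)
         for g in exclusion.genome_ids}
        if seed_word_size is not None else {}
    )
    for cand in candidates:
        seq = seq_by_id.get(cand.gene_id)
        if seq is None:
            raise KeyError(f"candidate {cand.gene_id!r} absent from reference GenomeSet")
        qk = kmer_set(seq, seed_word_size) if seed_word_size is not None else None
        cand.exclusion_hit = False
        for genome_id in exclusion.genome_ids:
            hit = best_hit(seq, cand.gene_id, genome_id,
                           exclusion.genomes[genome_id], scoring,
                           seed_word_size=seed_word_size, query_kmers=qk,
                           seed_index=indexes.get(genome_id))
            if _passes(hit, identity_min, coverage_min, len(seq), min_score_frac):
                cand.exclusion_hit = True
                cand.best_hits[genome_id] = hit
                break
    return candidates


def rank_and_select(candidates: list[MarkerCandidate], k: int) -> list[MarkerCandidate]:
    """Top-k surviving markers by conservation score, ties by gene id.

    Only conserved candidates without an exclusion hit participate.
    Ranks are assigned 1..n on the returned list.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    markers = [c for c in candidates if c.is_marker]
    markers.sort(key=lambda c: (-c.conservation_score, c.gene_id))
    selected = markers[: min(k, len(markers))]
    for rank, cand in enumerate(selected, start=1):
        cand.rank = rank
    return selected
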