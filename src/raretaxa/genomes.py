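"""Containers for gene collections grouped by genome.

A :class:`GenomeSet` is the pan-genome universe the marker-discovery
stage operates on: a mapping from genome id to a list of gene records,
labelled by clade role (``reference``, ``inclusion`` or ``exclusion``).
Gene ids are unique within a genome; across genomes the composite key
``genomeID|geneID`` (also the FASTA header convention) is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

NUCLEOTIDE_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sequence_alphabet(seq: str) -> str:
    """Classify a sequence as 'nucleotide' or 'protein' (nucleotide wins on overlap)."""
    letters = set(seq)
    if letters <= NUCLEOTIDE_ALPHABET:
        return "nucleotide"
    if letters <= PROTEIN_ALPHABET:
        return "protein"
    raise ValueError(f"sequence contains characters outside both alphabets: {sorted(letters - PROTEIN_ALPHABET)}")


@dataclass
class GeneRecord:
    """A single gene: id, nucleotide (or protein) sequence, optional translation."""

    gene_id: str
    sequence: str
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        sequence_alphabet(self.sequence)  # raises on illegal characters

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeSet:
    """Named genomes, each a list of gene records, with a clade label."""

    genomes: dict[str, list[GeneRecord]] = field(default_factory=dict)
    clade_label: str = "inclusion"

    _VALID_LABELS = ("inclusion", "exclusion", "reference")

    def __post_init__(self) -> None:
        if self.clade_label not in self._VALID_LABELS:
            raise ValueError(f"clade_label must be one of {self._VALID_LABELS}")
        for genome_id, genes in self.genomes.items():
            ids = [g.gene_id for g in genes]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate gene ids within genome {genome_id!r}")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def add_gene(self, genome_id: str, record: GeneRecord) -> None:
        genes = self.genomes.setdefault(genome_id, [])
        if any(g.gene_id == record.gene_id for g in genes):
            raise ValueError(f"duplicate gene id {record.gene_id!r} in genome {genome_id!r}")
        genes.append(record)

    def subset(self, genome_ids: list[str], clade_label: Optional[str] = None) -> "GenomeSet":
        missing = [g for g in genome_ids if g not in self.genomes]
        if missing:
            raise KeyError(f"genomes not present: {missing}")
        return GenomeSet(
            genomes={g: list(self.genomes[g]) for g in genome_ids},
            clade_label=clade_label or self.clade_label,
        )

    def iter_genes(self) -> Iterator[tuple[str, GeneRecord]]:
        for genome_id, genes in self.genomes.items():
            for record in genes:
                yield genome_id, record
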