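"""In-silico tryptic digestion and clade-unique peptide calling.

Protein-level evidence for a taxon rests on *unique* (proteotypic)
peptides: tryptic peptides that occur in the taxon's proteome and in no
background proteome.  Because a short peptide matched at 100% identity
over its full length is exactly a substring of a protein, uniqueness is
decided by exact substring search rather than heuristic alignment.

Digestion follows the standard trypsin rule — cleave C-terminal to K
or R except when the next residue is P — emitting all peptides with up
to ``max_missed`` internal missed cleavage sites and length >=
``min_length``.  The identification filters mirror common
mass-spectrometry search settings: peptide length >= 4, at most two
missed cleavages, and a +/-15 ppm precursor mass tolerance.

The eighteen published human-SFB unique peptides (identified by LC-MS
from ileal luminal fluids) ship as package data; all eighteen pass the
stated filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from pyteomics import mass as _pyteomics_mass

from .genomes import PROTEIN_ALPHABET

__all__ = [
    "Peptide",
    "UniquenessVerdict",
    "digest",
    "missed_cleavage_count",
    "monoisotopic_mass",
    "ppm_match",
    "call_unique_peptides",
    "load_reference_unique_peptides",
]


def _check_protein(seq: str) -> str:
    if not seq:
        raise ValueError("empty peptide/protein sequence")
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return seq


def missed_cleavage_count(peptide: str) -> int:
    """Internal (non-C-terminal) K/R residues not followed by P."""
    peptide = _check_protein(peptide)
    return sum(
        1
        for i in range(len(peptide) - 1)
        if peptide[i] in "KR" and peptide[i + 1] != "P"
    )


def monoisotopic_mass(peptide: str) -> float:
    """Monoisotopic peptide mass in Da (residue masses + one water)."""
    return float(_pyteomics_mass.fast_mass(_check_protein(peptide)))


def ppm_match(theoretical: float, observed: float, tolerance_ppm: float = 15.0) -> bool:
    """True iff |observed - theoretical| / theoretical <= tolerance_ppm * 1e-6 (inclusive)."""
    if theoretical <= 0 or observed <= 0:
        raise ValueError("masses must be > 0")
    return abs(observed - theoretical) / theoretical * 1e6 <= tolerance_ppm


@dataclass
class Peptide:
    sequence: str
    parent_protein_ids: set[str] = field(default_factory=set)
    missed_cleavages: int = 0
    monoisotopic_mass_da: float = 0.0

    def __post_init__(self) -> None:
        self.sequence = _check_protein(self.sequence)
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


def _cleavage_sites(protein: str) -> list[int]:
    """Positions after which trypsin cuts (0-based index of the K/R)."""
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def digest(
    protein: str,
    max_missed: int = 2,
    min_length: int = 4,
    protein_id: str = "protein",
) -> list[Peptide]:
    """Tryptic peptides of one protein with up to max_missed missed cleavages.

    Fully-cleaved fragments are the stretches between consecutive
    cleavage sites; a peptide with m missed cleavages spans m+1
    consecutive fragments.  Output is ordered by (start, end); length
    filtering happens after enumeration.
    """
    protein = _check_protein(protein)
    if max_missed < 0 or min_length < 1:
        raise ValueError("max_missed must be >= 0 and min_length >= 1")
    bounds = [0] + [s + 1 for s in _cleavage_sites(protein)] + [len(protein)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            seq = protein[bounds[i]:bounds[j]]
            if len(seq) < min_length:
                continue
            peptides.append(Peptide(
                sequence=seq,
                parent_protein_ids={protein_id},
                missed_cleavages=m,
                monoisotopic_mass_da=monoisotopic_mass(seq),
            ))
    return peptides


@dataclass
class UniquenessVerdict:
    peptide: str
    inclusion_matches: set[str]
    background_matches: set[str]

    @property
    def unique(self) -> bool:
        return len(self.inclusion_matches) >= 1 and len(self.background_matches) == 0


def _matches(peptide: str, proteome: dict[str, str]) -> set[str]:
    return {pid for pid, seq in proteome.items() if peptide in seq}


def call_unique_peptides(
    peptides,
    inclusion_proteome: dict[str, str],
    background_proteomes: dict[str, str],
    min_length: int = 4,
    max_missed: int = 2,
) -> list[UniquenessVerdict]:
    """Filter candidate peptides, then decide uniqueness by substring search.

    peptides: iterable of sequences (str) or Peptide objects.  A peptide
    survives filtering when length >= min_length and its internal
    missed-cleavage count <= max_missed; it is unique when it occurs in
    at least one inclusion protein and no background protein.
    """
    if not inclusion_proteome:
        raise ValueError("inclusion proteome is empty")
    inclusion = {pid: _check_protein(seq) for pid, seq in inclusion_proteome.items()}
    background = {pid: _check_protein(seq) for pid, seq in background_proteomes.items()}
    verdicts = []
    for pep in peptides:
        seq = pep.sequence if isinstance(pep, Peptide) else _check_protein(pep)
        if len(seq) < min_length or missed_cleavage_count(seq) > max_missed:
            continue
        verdicts.append(UniquenessVerdict(
            peptide=seq,
            inclusion_matches=_matches(seq, inclusion),
            background_matches=_matches(seq, background),
        ))
    return verdicts


def load_reference_unique_peptides() -> pd.DataFrame:
    """The 18 published human-SFB unique peptides (peptide, protein_name)."""
    with resources.files("raretaxa.data").joinpath("sfb_unique_peptides.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
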