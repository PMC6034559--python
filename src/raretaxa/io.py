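"""Readers and writers for the formats the pipeline touches.

FASTA (via Biopython, 60-column wrapped, ids as the first
whitespace-delimited header token; genome-set headers use the
``genomeID|geneID`` convention), CSV (comma, UTF-8, header row; TSV
accepted on input) and the JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomes import GeneRecord, GenomeSet, sequence_alphabet
from .qpcr import QpcrRun

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genomeset",
    "write_genomeset",
    "read_proteome",
    "write_proteome",
    "read_table",
    "write_qpcr_run",
    "read_qpcr_run",
    "sha256_file",
]


def read_fasta(path, alphabet: str | None = None) -> list[tuple[str, str, str]]:
    """Parse FASTA into (id, description, sequence) triples.

    Sequences are uppercased; the id is the first whitespace token of
    the header.  Raises on an empty file, duplicate ids, or characters
    outside the declared alphabet ('nucleotide' or 'protein').
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet is not None and sequence_alphabet(seq) != alphabet:
            raise ValueError(f"record {rec.id!r} is not {alphabet}")
        records.append((rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write (id, description, sequence) triples, wrapped at `width` columns."""
    seq_records = []
    for rec_id, description, seq in records:
        desc = description[len(rec_id):].strip() if description.startswith(rec_id) else description
        seq_records.append(SeqRecord(Seq(seq), id=rec_id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def write_genomeset(genomes: GenomeSet, path) -> None:
    """One FASTA for a whole genome set; headers are genomeID|geneID."""
    records = []
    for genome_id in genomes.genome_ids:
        for gene in genomes.genomes[genome_id]:
            records.append((f"{genome_id}|{gene.gene_id}", "", gene.sequence))
    write_fasta(records, path)


def read_genomeset(path, clade_label: str = "inclusion") -> GenomeSet:
    gs = GenomeSet(clade_label=clade_label)
    for rec_id, _, seq in read_fasta(path, alphabet="nucleotide"):
        if "|" not in rec_id:
            raise ValueError(f"header {rec_id!r} lacks the genomeID|geneID convention")
        genome_id, gene_id = rec_id.split("|", 1)
        gs.add_gene(genome_id, GeneRecord(gene_id, seq))
    return gs


def write_proteome(proteome: dict[str, str], path) -> None:
    write_fasta([(pid, "", seq) for pid, seq in proteome.items()], path)


def read_proteome(path) -> dict[str, str]:
    return {rec_id: seq for rec_id, _, seq in read_fasta(path, alphabet="protein")}


def read_table(path) -> pd.DataFrame:
    """CSV reader that also accepts TSV (sniffed from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def write_qpcr_run(run: QpcrRun, curve_path, samples_path) -> None:
    run.curve_points.to_csv(curve_path, index=False)
    run.samples.to_csv(samples_path, index=False)


def read_qpcr_run(curve_path, samples_path, conversion_factor: float = 1.0) -> QpcrRun:
    return QpcrRun(
        curve_points=read_table(curve_path),
        samples=read_table(samples_path),
        conversion_factor=conversion_factor,
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
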