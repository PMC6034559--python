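"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a rare-commensal (SFB)
detection workflow without any external download:

* a pan-genome universe with planted conserved / clade-specific /
  exclusion-shared genes, so marker discovery has an exact answer key;
* qPCR standard curves and sample Cts from the log-linear model
  Ct = intercept + slope*log10(copies) + N(0, sd);
* an sIgA cohort whose two groups are log-normal around the published
  medians (118.60 μg/ml colonized, 69.21 μg/ml non-colonized);
* proteomes in which known unique peptides are embedded so that
  tryptic digestion releases them exactly, against a background
  proteome constructed to share no length->=4 substring with the
  inclusion proteome (outside deliberately planted shared decoys);
* two-group taxon abundance tables with directional shifts (Clostridia
  up with colonization, Bacteroides/Enterobacteriaceae up without) and
  higher evenness in the colonized group.

All generators are pure functions of (config, seed): one root seed,
with per-generator streams derived from fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomes import GeneRecord, GenomeSet, reverse_complement
from .peptides import load_reference_unique_peptides
from .qpcr import QpcrRun

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "generate_pangenome",
    "generate_siga_cohort",
    "generate_qpcr_run",
    "generate_proteomes",
    "generate_true_loads",
    "generate_abundance_tables",
]

# fixed per-generator stream offsets under the root seed
_STREAM_PANGENOME = 1
_STREAM_SIGA = 2
_STREAM_QPCR = 3
_STREAM_PROTEOME = 4
_STREAM_LOADS = 5
_STREAM_ABUNDANCE = 6

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all synthetic-data generators.

    Pan-genome defaults are desk-scale (5 inclusion genomes emulating
    the reference plus related strains, 3 exclusion genomes emulating
    close Clostridium relatives); cohort and qPCR defaults match the
    published study (group sizes 23/24, medians 118.60/69.21 μg/ml,
    a perfect-efficiency curve slope of -1/log10(2)).
    """

    seed: int = 0
    n_inclusion_genomes: int = 5
    n_exclusion_genomes: int = 3
    n_reference_genes: int = 30
    n_conserved: int = 12
    n_exclusion_shared: int = 4
    gene_length_bp: int = 300
    point_mutation_rate: float = 0.02
    siga_median_pos: float = 118.60
    siga_median_neg: float = 69.21
    siga_log_sd: float = 0.4
    n_pos_subjects: int = 23
    n_neg_subjects: int = 24
    curve_slope: float = -3.3219280948873623  # -1/log10(2): perfect doubling
    curve_intercept: float = 37.0
    ct_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        counts = (
            self.n_inclusion_genomes, self.n_exclusion_genomes,
            self.n_reference_genes, self.n_conserved, self.n_exclusion_shared,
            self.gene_length_bp, self.n_pos_subjects, self.n_neg_subjects,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_conserved > self.n_reference_genes:
            raise ValueError("n_conserved cannot exceed n_reference_genes")
        if self.n_exclusion_shared > self.n_conserved:
            raise ValueError("n_exclusion_shared cannot exceed n_conserved")
        if not (0.0 <= self.point_mutation_rate < 0.25):
            raise ValueError("point_mutation_rate must be in [0, 0.25)")
        if self.siga_median_pos <= 0 or self.siga_median_neg <= 0:
            raise ValueError("sIgA medians must be > 0")
        if self.siga_log_sd < 0:
            raise ValueError("siga_log_sd must be >= 0")
        if self.curve_slope >= 0:
            raise ValueError("amplification requires a negative curve slope")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """The answer key a generator buries in its output."""

    marker_gene_ids: set[str] = field(default_factory=set)
    conserved_gene_ids: set[str] = field(default_factory=set)
    exclusion_shared_gene_ids: set[str] = field(default_factory=set)
    planted_unique_peptides: list[str] = field(default_factory=list)
    planted_shared_peptides: list[str] = field(default_factory=list)
    true_loads: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conserved_gene_ids and self.marker_gene_ids != (
            self.conserved_gene_ids - self.exclusion_shared_gene_ids
        ):
            raise ValueError("marker ids must equal conserved minus exclusion-shared")

    def to_json(self, path) -> None:
        payload = {
            "marker_gene_ids": sorted(self.marker_gene_ids),
            "conserved_gene_ids": sorted(self.conserved_gene_ids),
            "exclusion_shared_gene_ids": sorted(self.exclusion_shared_gene_ids),
            "planted_unique_peptides": list(self.planted_unique_peptides),
            "planted_shared_peptides": list(self.planted_shared_peptides),
            "true_loads": dict(sorted(self.true_loads.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _random_gene(rng: np.random.Generator, length: int) -> str:
    return _NT[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float, indel_rate: float = 0.0) -> str:
    """Point substitutions at the given per-base rate; optional small indels."""
    if rate == 0.0 and indel_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _NT[_NT != arr[i]]
        arr[i] = rng.choice(choices)
    out = arr.tobytes().decode("ascii")
    if indel_rate > 0.0:
        chars = list(out)
        pos = np.nonzero(rng.random(len(chars)) < indel_rate)[0]
        for i in sorted(pos, reverse=True):
            if rng.random() < 0.5 and len(chars) > 1:
                del chars[i]
            else:
                chars.insert(i, "ACGT"[rng.integers(0, 4)])
        out = "".join(chars)
    return out


def generate_pangenome(
    config: SimulationConfig,
    indel_rate: float = 0.0,
) -> tuple[GenomeSet, GenomeSet, PlantedTruth]:
    """Plant a marker-discovery answer key in a synthetic pan-genome.

    The inclusion set holds the reference genome ('ref') plus
    n_inclusion_genomes - 1 related genomes, each carrying a mutated
    copy of every conserved reference gene (random orientation, opaque
    gene ids, shuffled order) among unrelated random genes.  Exclusion
    genomes carry copies of the exclusion-shared subset of conserved
    genes.  Markers = conserved minus exclusion-shared.
    """
    rng = _rng(config, _STREAM_PANGENOME)
    n_ref = config.n_reference_genes
    ref_ids = [f"g{i:03d}" for i in range(n_ref)]
    ref_seqs = {gid: _random_gene(rng, config.gene_length_bp) for gid in ref_ids}
    conserved = sorted(map(str, rng.choice(ref_ids, size=config.n_conserved, replace=False)))
    # genes can only be exclusion-shared if there is an exclusion genome to carry them
    n_shared = config.n_exclusion_shared if config.n_exclusion_genomes > 0 else 0
    shared = sorted(map(str, rng.choice(conserved, size=n_shared, replace=False)))

    inclusion = GenomeSet(clade_label="inclusion")
    for gid in ref_ids:
        inclusion.add_gene("ref", GeneRecord(gid, ref_seqs[gid]))

    def planted_copy(gid: str) -> str:
        seq = _mutate(rng, ref_seqs[gid], config.point_mutation_rate, indel_rate)
        return reverse_complement(seq) if rng.random() < 0.5 else seq

    for g in range(1, config.n_inclusion_genomes):
        genome_id = f"inc{g:02d}"
        genes = [planted_copy(gid) for gid in conserved]
        genes += [_random_gene(rng, config.gene_length_bp)
                  for _ in range(n_ref - config.n_conserved)]
        order = rng.permutation(len(genes))
        for k, idx in enumerate(order):
            inclusion.add_gene(genome_id, GeneRecord(f"orf{k:03d}", genes[idx]))

    exclusion = GenomeSet(clade_label="exclusion")
    for g in range(config.n_exclusion_genomes):
        genome_id = f"exc{g:02d}"
        genes = [planted_copy(gid) for gid in shared]
        genes += [_random_gene(rng, config.gene_length_bp)
                  for _ in range(n_ref - config.n_exclusion_shared)]
        order = rng.permutation(len(genes))
        for k, idx in enumerate(order):
            exclusion.add_gene(genome_id, GeneRecord(f"orf{k:03d}", genes[idx]))

    truth = PlantedTruth(
        marker_gene_ids=set(conserved) - set(shared),
        conserved_gene_ids=set(conserved),
        exclusion_shared_gene_ids=set(shared),
    )
    return inclusion, exclusion, truth


def generate_siga_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Two-group sIgA cohort, log-normal around the configured group medians.

    Concentrations are positive and right-skewed, so each group is
    log-normal with log-median ln(median) and log-sd siga_log_sd.  Ages
    are integer months uniform on 8..48.  Columns: subject_id,
    age_months, sfb_status, siga_ug_ml.
    """
    rng = _rng(config, _STREAM_SIGA)
    rows = []
    for status, n, median, prefix in (
        ("positive", config.n_pos_subjects, config.siga_median_pos, "P"),
        ("negative", config.n_neg_subjects, config.siga_median_neg, "N"),
    ):
        ages = rng.integers(8, 49, size=n)
        siga = rng.lognormal(mean=math.log(median), sigma=config.siga_log_sd, size=n)
        for i in range(n):
            rows.append({
                "subject_id": f"{prefix}{i + 1:03d}",
                "age_months": int(ages[i]),
                "sfb_status": status,
                "siga_ug_ml": float(siga[i]),
            })
    return pd.DataFrame(rows)


def generate_true_loads(config: SimulationConfig, n_positive: int = 12,
                        n_negative: int = 12) -> dict[str, float]:
    """True SFB loads (CFU/ml): positives log-uniform on 1e4..1e6 (the
    observed colonized range), negatives log-uniform on 1e2..1e4."""
    rng = _rng(config, _STREAM_LOADS)
    loads = {}
    for i in range(n_positive):
        loads[f"S{i + 1:03d}"] = float(10.0 ** rng.uniform(4.0, 6.0))
    for i in range(n_negative):
        loads[f"S{n_positive + i + 1:03d}"] = float(10.0 ** rng.uniform(2.0, 4.0))
    return loads


def generate_qpcr_run(
    config: SimulationConfig,
    true_loads: dict[str, float],
    total_loads: dict[str, float] | None = None,
    curve_replicates: int = 3,
    sample_replicates: int = 2,
    conversion_factor: float = 1.0,
) -> QpcrRun:
    """Standard-curve points and sample Cts from the log-linear Ct model.

    Curve points sit at 10^1..10^7 copies for both the taxon-specific
    ('SFB') and total-bacteria ('universal') targets; sample Cts apply
    the same model to the true loads (total defaults to 1e11 CFU/ml for
    every sample).  Gaussian Ct noise with sd config.ct_noise_sd.
    """
    if any(v <= 0 for v in true_loads.values()):
        raise ValueError("true loads must be > 0")
    rng = _rng(config, _STREAM_QPCR)
    if total_loads is None:
        total_loads = {s: 1e11 for s in true_loads}

    def model_ct(copies: float) -> float:
        ct = config.curve_intercept + config.curve_slope * math.log10(copies)
        if config.ct_noise_sd > 0:
            ct += rng.normal(0.0, config.ct_noise_sd)
        return ct

    curve_rows = []
    for target in ("SFB", "universal"):
        for exponent in range(1, 8):
            copies = 10.0 ** exponent
            for rep in range(1, curve_replicates + 1):
                curve_rows.append({"target": target, "copies": copies,
                                   "ct": model_ct(copies), "replicate": rep})
    sample_rows = []
    for sample_id in sorted(true_loads):
        for target, load in (("SFB", true_loads[sample_id]),
                             ("universal", total_loads[sample_id])):
            copies = load / conversion_factor
            for rep in range(1, sample_replicates + 1):
                sample_rows.append({"sample_id": sample_id, "target": target,
                                    "ct": model_ct(copies), "replicate": rep})
    return QpcrRun(
        curve_points=pd.DataFrame(curve_rows),
        samples=pd.DataFrame(sample_rows),
        conversion_factor=conversion_factor,
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _protein_avoiding(rng: np.random.Generator, length: int,
                      forbidden_4mers: set[str]) -> str:
    """Random protein containing no 4-mer from the forbidden set (greedy with backtracking)."""
    seq: list[str] = []
    stalls = 0
    while len(seq) < length:
        for idx in rng.permutation(len(_AA)):
            cand = _AA[idx]
            if len(seq) >= 3 and "".join(seq[-3:]) + cand in forbidden_4mers:
                continue
            seq.append(cand)
            break
        else:
            if not seq:
                raise RuntimeError("cannot extend protein: forbidden set too dense")
            seq.pop()
            stalls += 1
            if stalls > 100 * length:
                raise RuntimeError("backtracking limit exceeded")
    return "".join(seq)


def _kmers(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def generate_proteomes(
    config: SimulationConfig,
    planted_peptides: list[str] | None = None,
    n_extra_inclusion_proteins: int = 4,
    n_background_proteins: int = 20,
    protein_length: int = 240,
    n_shared_decoys: int = 2,
) -> tuple[dict[str, str], dict[str, str], PlantedTruth]:
    """Proteomes with planted unique peptides (default: the 18 published ones).

    Each planted peptide is embedded in one inclusion protein flanked
    so trypsin releases it exactly: the preceding residue is K/R (the
    peptide starts the protein if it begins with P), the following
    residue is not P (the peptide ends the protein if its last residue
    is not K/R).  Background proteins avoid every 4-mer of the
    inclusion proteome, so with n_shared_decoys=0 the two proteomes
    share no peptide of length >= 4; shared decoy peptides, planted in
    both proteomes, exercise the non-unique branch of uniqueness calls.
    """
    rng = _rng(config, _STREAM_PROTEOME)
    if planted_peptides is None:
        planted_peptides = list(load_reference_unique_peptides()["peptide"])
    bad = [p for p in planted_peptides if set(p) - set(_AA) or not p]
    if bad:
        raise ValueError(f"peptides with non-standard residues: {bad}")

    flank = max(30, protein_length // 4)

    def embed(peptide: str) -> str:
        if peptide[0] == "P":
            prefix = ""
        else:
            body = _random_protein(rng, flank - 1)
            prefix = body + ("K" if rng.random() < 0.5 else "R")
        if peptide[-1] in "KR":
            suffix = _random_protein(rng, flank)
            while suffix[0] == "P":
                suffix = _random_protein(rng, flank)
        else:
            suffix = ""
        return prefix + peptide + suffix

    inclusion: dict[str, str] = {}
    for i, pep in enumerate(planted_peptides, 1):
        inclusion[f"sfb_prot{i:03d}"] = embed(pep)
    for i in range(1, n_extra_inclusion_proteins + 1):
        inclusion[f"sfb_extra{i:03d}"] = _random_protein(rng, protein_length)

    decoys = []
    for i in range(n_shared_decoys):
        decoy = _random_protein(rng, 9) + ("K" if rng.random() < 0.5 else "R")
        while decoy[0] == "P":
            decoy = _random_protein(rng, 9) + "K"
        decoys.append(decoy)
        inclusion[f"sfb_decoyhost{i + 1:03d}"] = embed(decoy)

    forbidden = set()
    for seq in inclusion.values():
        forbidden |= _kmers(seq)

    background: dict[str, str] = {}
    for i in range(1, n_background_proteins + 1):
        background[f"bg_prot{i:03d}"] = _protein_avoiding(rng, protein_length, forbidden)
    for i, decoy in enumerate(decoys):
        host = f"bg_prot{(i % n_background_proteins) + 1:03d}"
        seq = background[host]
        background[host] = seq[:protein_length // 2] + decoy + seq[protein_length // 2:]

    # planted peptides must not leak into the background by construction
    for pep in planted_peptides:
        assert all(pep not in seq for seq in background.values())

    truth = PlantedTruth(
        planted_unique_peptides=list(planted_peptides),
        planted_shared_peptides=decoys,
    )
    return inclusion, background, truth


#: genus-level taxa with published directional shifts under colonization
ABUNDANCE_TAXA_UP = ("Clostridia", "Coriobacteriia", "Deltaproteobacteria")
ABUNDANCE_TAXA_DOWN = ("Bacteroides", "Escherichia", "Klebsiella")
ABUNDANCE_TAXA_NEUTRAL = ("Eubacterium", "Prevotella", "Roseburia", "Other")


def generate_abundance_tables(
    config: SimulationConfig,
    n_pos_samples: int = 3,
    n_neg_samples: int = 3,
    effect: float = 3.0,
    concentration: float = 60.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group relative-abundance tables with directional taxon shifts.

    Rows are samples, columns taxa, values proportions summing to 1 per
    row.  Dirichlet draws: taxa in ABUNDANCE_TAXA_UP get their base
    concentration multiplied by ``effect`` in the colonized group (and
    ABUNDANCE_TAXA_DOWN in the non-colonized group, whose remaining
    mass also concentrates, lowering its evenness and hence Shannon
    diversity relative to the colonized group).
    """
    rng = _rng(config, _STREAM_ABUNDANCE)
    taxa = list(ABUNDANCE_TAXA_UP + ABUNDANCE_TAXA_DOWN + ABUNDANCE_TAXA_NEUTRAL)
    base = np.ones(len(taxa))
    rows, groups, index = [], [], []
    for status, n in (("positive", n_pos_samples), ("negative", n_neg_samples)):
        alpha = base.copy()
        if status == "positive":
            for t in ABUNDANCE_TAXA_UP:
                alpha[taxa.index(t)] *= effect
        else:
            for t in ABUNDANCE_TAXA_DOWN:
                alpha[taxa.index(t)] *= effect * 2.0
        for i in range(n):
            rows.append(rng.dirichlet(alpha * concentration / alpha.sum()))
            groups.append(status)
            index.append(f"{status[:3]}_{i + 1:02d}")
    table = pd.DataFrame(rows, columns=taxa, index=index)
    return table, pd.Series(groups, index=index, name="sfb_status")
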