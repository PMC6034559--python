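"""End-to-end orchestration of the detection pipeline on synthetic data.

simulate -> discover markers -> design and validate primers -> quantify
by qPCR -> digest and call unique peptides -> cohort statistics.  Each
stage writes a CSV; a JSON manifest records the seed, all parameters
and the checksums of every file so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import compare_groups, prevalence_table, shannon_index
from .io import sha256_file, write_genomeset, write_json, write_proteome, write_qpcr_run
from .markers import (
    DEFAULT_COVERAGE_MIN, DEFAULT_COVERAGE_MIN_EXCL,
    DEFAULT_IDENTITY_MIN, DEFAULT_IDENTITY_MIN_EXCL,
    conservation_scan, rank_and_select, subtract_exclusion,
)
from .peptides import call_unique_peptides, digest
from .primers import PrimerConstraints, design_primers, insilico_pcr, specificity_check
from .qpcr import POSITIVITY_THRESHOLD_CFU_PER_ML, metagenome_detectability, quantify_run
from .simulate import (
    SimulationConfig, generate_abundance_tables, generate_pangenome,
    generate_proteomes, generate_qpcr_run, generate_siga_cohort, generate_true_loads,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs; JSON-serializable."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "pipeline_out"
    k_markers: int = 5
    identity_min: float = DEFAULT_IDENTITY_MIN
    coverage_min: float = DEFAULT_COVERAGE_MIN
    identity_min_excl: float = DEFAULT_IDENTITY_MIN_EXCL
    coverage_min_excl: float = DEFAULT_COVERAGE_MIN_EXCL
    max_mismatches_per_primer: int = 2
    positivity_threshold: float = POSITIVITY_THRESHOLD_CFU_PER_ML
    group_test: str = "student_t"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # the output location is run metadata, not part of the run's identity
        d.pop("outdir", None)
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name, outdir, fn):
    try:
        return fn()
    except Exception as exc:
        (Path(outdir) / "FAILED").write_text(f"stage {name}: {exc}\n")
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns {output name: path} for the result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    outputs: dict[str, str] = {}

    def simulate():
        simdir = outdir / "simulated"
        simdir.mkdir(exist_ok=True)
        inclusion, exclusion, truth = generate_pangenome(sim)
        cohort = generate_siga_cohort(sim)
        loads = generate_true_loads(sim)
        run = generate_qpcr_run(sim, loads)
        incl_prot, bg_prot, prot_truth = generate_proteomes(sim)
        abundance, groups = generate_abundance_tables(sim)
        truth.planted_unique_peptides = prot_truth.planted_unique_peptides
        truth.planted_shared_peptides = prot_truth.planted_shared_peptides
        truth.true_loads = loads
        write_genomeset(inclusion, simdir / "inclusion_genomes.fasta")
        write_genomeset(exclusion, simdir / "exclusion_genomes.fasta")
        write_proteome(incl_prot, simdir / "inclusion_proteome.fasta")
        write_proteome(bg_prot, simdir / "background_proteome.fasta")
        cohort.to_csv(simdir / "cohort.csv", index=False)
        write_qpcr_run(run, simdir / "qpcr_curve.csv", simdir / "qpcr_samples.csv")
        abundance.assign(sfb_status=groups).to_csv(simdir / "abundance.csv")
        truth.to_json(simdir / "planted_truth.json")
        return inclusion, exclusion, truth, cohort, run, incl_prot, bg_prot, abundance, groups

    (inclusion, exclusion, truth, cohort, run,
     incl_prot, bg_prot, abundance, groups) = _stage("simulate", outdir, simulate)

    def discover():
        reference = inclusion.subset(["ref"], clade_label="reference")
        others = inclusion.subset([g for g in inclusion.genome_ids if g != "ref"])
        candidates = conservation_scan(reference, others,
                                       config.identity_min, config.coverage_min)
        candidates = subtract_exclusion(candidates, exclusion,
                                        config.identity_min_excl, config.coverage_min_excl,
                                        reference=reference)
        selected = rank_and_select(candidates, config.k_markers)
        table = pd.DataFrame([
            {"gene_id": c.gene_id, "conserved": c.conserved,
             "exclusion_hit": c.exclusion_hit,
             "conservation_score": round(c.conservation_score, 6),
             "rank": c.rank if c.rank is not None else ""}
            for c in sorted(candidates, key=lambda c: c.gene_id)
        ])
        table.to_csv(outdir / "markers.csv", index=False)
        return reference, selected

    reference, selected = _stage("discover-markers", outdir, discover)
    outputs["markers"] = str(outdir / "markers.csv")

    def primers():
        seq_by_id = {r.gene_id: r.sequence for _, r in reference.iter_genes()}
        non_ref = inclusion.subset([g for g in inclusion.genome_ids if g != "ref"])
        rows = []
        for cand in selected:
            pairs = design_primers(seq_by_id[cand.gene_id], PrimerConstraints(),
                                   target_gene_id=cand.gene_id, max_pairs=1)
            for pair in pairs:
                if exclusion.n_genomes == 0:
                    # no exclusion clade: only universality can be judged
                    hits = insilico_pcr(pair, non_ref, config.max_mismatches_per_primer)
                    covered = {h.genome_id for h in hits}
                    verdict = ("specific" if covered >= set(non_ref.genome_ids)
                               else "non_universal")
                else:
                    verdict = specificity_check(pair, non_ref, exclusion,
                                                config.max_mismatches_per_primer)
                rows.append({
                    "name": pair.name, "target_gene_id": pair.target_gene_id,
                    "forward": pair.forward, "reverse": pair.reverse,
                    "tm_forward": pair.tm_forward, "tm_reverse": pair.tm_reverse,
                    "gc_forward": round(pair.gc_forward, 2),
                    "gc_reverse": round(pair.gc_reverse, 2),
                    "product_length": pair.expected_product_length,
                    "penalty": round(pair.penalty, 4), "specificity": verdict,
                })
        pd.DataFrame(rows).to_csv(outdir / "primers.csv", index=False)

    _stage("design-primers", outdir, primers)
    outputs["primers"] = str(outdir / "primers.csv")

    def quant():
        table = quantify_run(run, threshold=config.positivity_threshold)
        table["true_load"] = table["sample_id"].map(truth.true_loads)
        table.to_csv(outdir / "quant.csv", index=False)
        return table

    quant_table = _stage("quantify", outdir, quant)
    outputs["quant"] = str(outdir / "quant.csv")

    def peptides():
        candidate_peps = sorted({
            p.sequence
            for prot_id, seq in incl_prot.items()
            for p in digest(seq, protein_id=prot_id)
        })
        verdicts = call_unique_peptides(candidate_peps, incl_prot, bg_prot)
        table = pd.DataFrame([
            {"peptide": v.peptide, "unique": v.unique,
             "n_inclusion_proteins": len(v.inclusion_matches),
             "n_background_proteins": len(v.background_matches),
             "planted": v.peptide in set(truth.planted_unique_peptides)}
            for v in verdicts
        ])
        table.to_csv(outdir / "unique_peptides.csv", index=False)

    _stage("uniqueness", outdir, peptides)
    outputs["unique_peptides"] = str(outdir / "unique_peptides.csv")

    def stats():
        rows = []
        prev = prevalence_table(cohort)
        for _, r in prev.iterrows():
            rows.append({"section": "prevalence", "key": r["age_bin"],
                         "value": r["percent_positive"]})
        pos = cohort.loc[cohort["sfb_status"] == "positive", "siga_ug_ml"]
        neg = cohort.loc[cohort["sfb_status"] == "negative", "siga_ug_ml"]
        cmp = compare_groups(pos, neg, test=config.group_test)
        rows += [
            {"section": "siga", "key": "median_positive", "value": cmp.median_a},
            {"section": "siga", "key": "median_negative", "value": cmp.median_b},
            {"section": "siga", "key": "pvalue", "value": cmp.pvalue},
            {"section": "siga", "key": "test", "value": cmp.test},
        ]
        shannon = abundance.apply(shannon_index, axis=1)
        for status in ("positive", "negative"):
            rows.append({"section": "shannon", "key": f"mean_{status}",
                         "value": shannon[groups == status].mean()})
        rows.append({"section": "qpcr", "key": "n_positive_samples",
                     "value": int(quant_table["positive"].sum())})
        rows.append({"section": "detectability",
                     "key": "min_rel_abundance_4gb_1pct",
                     "value": metagenome_detectability(4e9, 1.6e6, 0.01)})
        pd.DataFrame(rows).to_csv(outdir / "cohort_stats.csv", index=False)

    _stage("cohort-stats", outdir, stats)
    outputs["cohort_stats"] = str(outdir / "cohort_stats.csv")

    def manifest():
        files = sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
        write_json({
            "package": "raretaxa",
            "version": __version__,
            "seed": sim.seed,
            "config": config.to_dict(),
            "checksums": {f: sha256_file(outdir / f) for f in files},
        }, outdir / "manifest.json")

    _stage("manifest", outdir, manifest)
    outputs["manifest"] = str(outdir / "manifest.json")
    return outputs
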