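"""End-to-end orchestration: simulate inputs, run all stages, write reports.

Stage order: search-space construction (six-frame translation + decoys) →
digestion-backed peptide mapping → PSM validation (mixture posterior +
decoy FDR) → parsimony protein inference → database-origin attribution →
annotation transfer. All stage outputs are plain files (FASTA/TSV/JSON);
identical configuration and inputs give byte-identical outputs, and every
run writes its resolved configuration beside the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import yaml

from sstdbkit import synthetic_data as synth
from sstdbkit.annotation import parse_blast_tabular, summarize_species, transfer_annotation
from sstdbkit.attribution import build_report, detect_conflicts
from sstdbkit.digestion import digest, digest_database
from sstdbkit.protein_inference import cluster_fdr, group_parsimony, map_peptides
from sstdbkit.psm_validation import (
    ACCEPTED,
    assign_posteriors,
    filter_psms,
    read_psm_table,
    write_psm_table,
)
from sstdbkit.sequence_db import (
    SSTDB,
    SearchDatabase,
    concatenate_dbs,
    orfs_to_entries,
    read_fasta,
    six_frame_translate,
    write_fasta,
)
from sstdbkit.synthetic_data import SimulationConfig

logger = logging.getLogger("sstdbkit")


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one place.

    Defaults are the standard search settings: minimum ORF length 60
    residues (strictly longer kept), trypsin with at most 2 missed
    cleavages, ±10 ppm precursor tolerance, 0.6 Da fragment tolerance
    (carried for completeness; inert because spectra are not simulated),
    95% posterior-probability acceptance, and annotation transfer at
    e-value 1e-4.
    """

    transcripts: Optional[str] = None
    orthologues: Optional[str] = None
    contaminants: Optional[str] = None
    psms: Optional[str] = None
    blast: Optional[str] = None
    min_orf: int = 60
    max_missed: int = 2
    precursor_ppm: float = 10.0
    fragment_da: float = 0.6  # inert: no spectra are simulated
    probability_threshold: float = 0.95
    annotation_e_threshold: float = 1e-4
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    with_decoys: bool = True
    rng_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def build_database(config: PipelineConfig) -> SearchDatabase:
    """Six-frame translate the transcripts and concatenate all sources."""
    transcripts = read_fasta(config.transcripts) if config.transcripts else []
    orthologues = read_fasta(config.orthologues, default_origin="VPDB") if config.orthologues else []
    contaminants = (
        read_fasta(config.contaminants, default_origin="CONTAMINANT")
        if config.contaminants
        else []
    )
    orfs = []
    for t in transcripts:
        orfs.extend(six_frame_translate(t, min_len=config.min_orf))
    sstdb = orfs_to_entries(orfs)
    db = concatenate_dbs(sstdb, orthologues, contaminants, with_decoys=config.with_decoys)
    logger.info(
        "database: %d transcripts -> %d ORFs; %d orthologues; %d contaminants; "
        "%d entries total",
        len(transcripts),
        len(sstdb),
        len(orthologues),
        len(contaminants),
        len(db),
    )
    return db


def simulate(sim: SimulationConfig, outdir: str | Path, min_orf: int = 60) -> dict[str, Path]:
    """Generate a complete synthetic input bundle with truth sidecars.

    Writes transcripts, orthologue and contaminant FASTAs, a PSM-TSV whose
    accessions resolve against the database the pipeline will build from
    those same files, a fabricated BLAST table, ground-truth sidecar TSVs
    and the resolved simulation config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteome = synth.generate_proteome(sim)
    transcripts, transcript_truth = synth.generate_transcripts(proteome, sim)
    orthologues, orthologue_map = synth.generate_orthologue_db(proteome, sim)
    contaminants = synth.generate_contaminants(sim)

    # Build the same database the pipeline will, to derive peptide pools
    # whose accession lists resolve against it.
    orfs = []
    for t in transcripts:
        orfs.extend(six_frame_translate(t, min_len=min_orf))
    sstdb = orfs_to_entries(orfs)
    db = concatenate_dbs(sstdb, orthologues, contaminants, with_decoys=True)
    index = digest_database(
        db.entries,
        max_missed=2,
        min_len=sim.min_peptide_length,
        max_len=sim.max_peptide_length,
    )

    # Target pool: ground-truth tryptic peptides present in >=1 target entry.
    target_pool = []
    seen = set()
    for prot in proteome:
        for pep in digest(
            prot.sequence,
            max_missed=2,
            min_len=sim.min_peptide_length,
            max_len=sim.max_peptide_length,
        ):
            key = pep.il_key
            if key in seen:
                continue
            seen.add(key)
            accs = index.get(key, set())
            target_accs = tuple(sorted(a for a in accs if not db[a].is_decoy))
            if target_accs:
                target_pool.append((pep.sequence, target_accs))
    # Decoy pool: peptides found only in decoy entries.
    decoy_pool = []
    for key in sorted(index):
        accs = index[key]
        if all(db[a].is_decoy for a in accs):
            decoy_pool.append((key, tuple(sorted(accs))))

    rows, labels = synth.generate_psms(target_pool, decoy_pool, sim)

    # BLAST table for the ORFs that carry a planted protein.
    truth_by_key = {
        (t.transcript_id, t.frame, t.start, t.end): t.protein_id
        for t in transcript_truth
        if t.protein_id is not None
    }
    query_truth = {
        e.accession: truth_by_key[e.source_transcript]
        for e in sstdb
        if e.source_transcript in truth_by_key
    }
    blast_hits = synth.generate_blast_hits(query_truth, sim)

    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "orthologues": outdir / "orthologues.fasta",
        "contaminants": outdir / "contaminants.fasta",
        "psms": outdir / "psms.tsv",
        "blast": outdir / "blast.tsv",
    }
    write_fasta(transcripts, paths["transcripts"])
    write_fasta(orthologues, paths["orthologues"])
    write_fasta(contaminants, paths["contaminants"])
    synth.write_psm_rows(rows, paths["psms"])
    from sstdbkit.annotation import write_blast_tabular

    write_blast_tabular(blast_hits, paths["blast"])
    truth = synth.GroundTruth(
        proteome=proteome,
        transcripts=transcript_truth,
        orthologue_map=orthologue_map,
        psm_labels=labels,
    )
    write_fasta(proteome, outdir / "truth_proteome.fasta")
    truth.write_sidecars(outdir)
    sim.to_yaml(outdir / "simulation_config.yaml")
    logger.info(
        "simulated %d proteins, %d transcripts, %d orthologue entries, %d PSMs",
        len(proteome),
        len(transcripts),
        len(orthologues),
        len(rows),
    )
    return paths


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every stage in order; returns the paths of the written outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "pipeline_config.yaml")
    out: dict[str, Path] = {}

    # Stage 1: search space.
    db = build_database(config)
    out["db"] = outdir / "db.fasta"
    write_fasta(db.entries, out["db"])
    out["db_report"] = outdir / "db_report.json"
    out["db_report"].write_text(json.dumps(db.counts(), indent=2, sort_keys=True) + "\n")

    # Stage 2+3: ingest PSMs, posterior validation, decoy FDR.
    psms = read_psm_table(config.psms, db)
    fit = assign_posteriors(psms)
    detect_conflicts(psms)
    accepted, psm_fdr, peptide_fdr = filter_psms(psms, threshold=config.probability_threshold)
    logger.info(
        "validation: %d PSM rows -> %d accepted (psmFDR %.2f%%, pepFDR %.2f%%)",
        len(psms),
        len(accepted),
        psm_fdr.fdr,
        peptide_fdr.fdr,
    )
    out["validated_psms"] = outdir / "validated_psms.tsv"
    write_psm_table(accepted, out["validated_psms"])

    # Stage 4: parsimony inference on accepted unique peptides.
    unique_peptides = sorted({p.peptide.il_key for p in accepted})
    mapping = map_peptides(
        unique_peptides,
        db,
        max_missed=config.max_missed,
        min_len=config.min_peptide_length,
        max_len=config.max_peptide_length,
    )
    clusters = group_parsimony(mapping, db)
    cfdr = cluster_fdr(clusters)
    logger.info(
        "inference: %d unique peptides -> %d clusters (protFDR %.2f%%)",
        len(unique_peptides),
        len(clusters),
        cfdr.fdr,
    )
    out["clusters"] = outdir / "clusters.tsv"
    with open(out["clusters"], "w") as fh:
        fh.write("cluster_id\trepresentative\tmembers\torigins\tn_peptides\tis_decoy\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.representative}\t{';'.join(c.member_accessions)}\t"
                f"{';'.join(sorted(c.origins))}\t{c.n_peptides}\t{int(c.is_decoy)}\n"
            )
    out["fdr_summary"] = outdir / "fdr_summary.json"
    out["fdr_summary"].write_text(
        json.dumps(
            {
                "psm": {"n_decoy": psm_fdr.n_decoy, "n_target": psm_fdr.n_target, "fdr_percent": psm_fdr.fdr},
                "peptide": {"n_decoy": peptide_fdr.n_decoy, "n_target": peptide_fdr.n_target, "fdr_percent": peptide_fdr.fdr},
                "protein_cluster": {"n_decoy": cfdr.n_decoy, "n_target": cfdr.n_target, "fdr_percent": cfdr.fdr},
                "mixture": {
                    "mu_incorrect": fit.mu_incorrect,
                    "mu_correct": fit.mu_correct,
                    "pi_correct": fit.pi_correct,
                    "degenerate": fit.degenerate,
                },
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    # Stage 5: database-origin attribution.
    report = build_report(psms, clusters)
    out["attribution"] = outdir / "attribution.json"
    out["attribution"].write_text(report.to_json() + "\n")
    out["attribution_table"] = outdir / "attribution.txt"
    out["attribution_table"].write_text(report.to_table() + "\n")
    ratio = report.enrichment_ratio
    logger.info(
        "attribution: enrichment ratio %s",
        "undefined" if ratio is None else f"{ratio:.1f}",
    )

    # Stage 6: annotation transfer onto SSTDB entries.
    if config.blast:
        sstdb_entries = [e for e in db.entries if e.origin == SSTDB and not e.is_decoy]
        hits = parse_blast_tabular(config.blast)
        records, annotated = transfer_annotation(
            sstdb_entries, hits, threshold=config.annotation_e_threshold
        )
        out["annotated_db"] = outdir / "annotated_sstdb.fasta"
        write_fasta(annotated, out["annotated_db"])
        out["species_summary"] = outdir / "species_summary.tsv"
        summarize_species(records).to_csv(out["species_summary"], sep="\t", index=False)
        n_annotated = sum(1 for r in records if r.annotated)
        logger.info("annotation: %d/%d SSTDB entries annotated", n_annotated, len(records))
    return out
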