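"""Synthetic ground-truth data for exercising the whole pipeline.

Real inputs to a proteogenomic search — an assembled transcriptome, a
cross-species orthologue database and a search engine's PSM export — are
large and carry no usable truth labels. This module generates all of them
at desk scale with the truth recorded: a random proteome; transcripts that
embed each protein as a reverse-translated CDS (random synonymous codons,
standard genetic code) flanked by untranslated sequence with in-frame stop
codons at the CDS boundaries, so six-frame ORF extraction recovers the
protein exactly; a divergent orthologue database covering a configurable
fraction of the proteome; contaminant entries; and PSM lists whose scores
are drawn from separate correct/incorrect Gaussian score distributions
(means 4 standard deviations apart by default — the score model is a
declared stand-in, since real search-engine score distributions are engine
internals).

Incorrect PSMs hit a random target or decoy peptide with equal probability,
the standard assumption that makes the concatenated target-decoy FDR
estimate calibrated against the recorded labels. Decoy entries never
receive correct-labeled PSMs.

Every generator is a pure function of (inputs, seed): a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from sstdbkit.annotation import BlastHit
from sstdbkit.sequence_db import (
    CONTAMINANT,
    SSTDB,
    VPDB,
    SequenceEntry,
    _CODON_TO_AA,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

# AA -> sorted list of synonymous codons (standard code); stops kept apart.
CODONS_BY_AA: dict[str, list[str]] = {}
STOP_CODONS: list[str] = []
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    if _aa == "*":
        STOP_CODONS.append(_codon)
    else:
        CODONS_BY_AA.setdefault(_aa, []).append(_codon)

# Species mnemonics used for fabricated BLAST subjects.
BLAST_SPECIES = ("ARATH", "ORYSJ", "PHYPA", "SELML", "SOLLC", "PICSI", "HUMAN")

# Distinct substreams so each generator is independently reproducible.
_STREAM_PROTEOME = 1
_STREAM_TRANSCRIPTS = 2
_STREAM_ORTHOLOGUES = 3
_STREAM_CONTAMINANTS = 4
_STREAM_PSMS = 5
_STREAM_BLAST = 6


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Score distributions default to N(0,1) for incorrect and N(4,1) for
    correct matches (4 sd separation). ``n_contaminants`` defaults to 260,
    the size of a standard MS contaminant list.
    """

    n_proteins: int = 200
    protein_length_mean: float = 350.0
    protein_length_sd: float = 100.0
    min_protein_length: int = 80
    n_noncoding_transcripts: int = 200
    noncoding_length_range: tuple[int, int] = (200, 1500)
    utr_length_range: tuple[int, int] = (20, 150)
    orthologue_fraction: float = 0.7
    orthologue_divergence: float = 0.1
    unrelated_fraction: float = 0.2  # of the final orthologue DB
    n_contaminants: int = 260
    contaminant_length: int = 150
    n_spectra: int = 10_000
    p_correct: float = 0.7
    correct_score_mean: float = 4.0
    correct_score_sd: float = 1.0
    incorrect_score_mean: float = 0.0
    incorrect_score_sd: float = 1.0
    min_peptide_length: int = 6  # detectability floor for emitted peptides
    max_peptide_length: int = 50
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("orthologue_fraction", "p_correct", "orthologue_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.unrelated_fraction < 1.0:
            raise ValueError("unrelated_fraction must lie in [0, 1)")
        for name in ("n_proteins", "n_noncoding_transcripts", "n_contaminants", "n_spectra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.protein_length_sd < 0 or self.protein_length_mean <= 0:
            raise ValueError("protein length parameters must be positive")
        if self.correct_score_sd <= 0 or self.incorrect_score_sd <= 0:
            raise ValueError("score standard deviations must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["noncoding_length_range"] = list(d["noncoding_length_range"])
        d["utr_length_range"] = list(d["utr_length_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("noncoding_length_range", "utr_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class TranscriptTruth:
    """Where (if anywhere) a transcript encodes a ground-truth protein."""

    transcript_id: str
    protein_id: Optional[str]  # None for non-coding transcripts
    frame: Optional[int]
    start: Optional[int]  # 0-based half-open on the forward strand
    end: Optional[int]


@dataclass(frozen=True)
class PsmRow:
    """One synthetic search-engine export row (PSM-TSV dialect)."""

    spectrum_id: str
    peptide: str
    mods: str
    score: float
    accessions: tuple[str, ...]


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must rediscover."""

    proteome: list[SequenceEntry] = field(default_factory=list)
    transcripts: list[TranscriptTruth] = field(default_factory=list)
    orthologue_map: dict[str, str] = field(default_factory=dict)  # orth acc -> protein id
    psm_labels: dict[str, bool] = field(default_factory=dict)  # spectrum id -> correct?

    def write_sidecars(self, directory: str | Path) -> None:
        directory = Path(directory)
        with open(directory / "truth_transcripts.tsv", "w") as fh:
            fh.write("transcript_id\tprotein_id\tframe\tstart\tend\n")
            for t in self.transcripts:
                fh.write(
                    f"{t.transcript_id}\t{t.protein_id or ''}\t"
                    f"{'' if t.frame is None else t.frame}\t"
                    f"{'' if t.start is None else t.start}\t"
                    f"{'' if t.end is None else t.end}\n"
                )
        with open(directory / "truth_orthologues.tsv", "w") as fh:
            fh.write("orthologue_accession\tprotein_id\n")
            for acc in sorted(self.orthologue_map):
                fh.write(f"{acc}\t{self.orthologue_map[acc]}\n")
        with open(directory / "truth_psm_labels.tsv", "w") as fh:
            fh.write("spectrum_id\tlabel\n")
            for sid, ok in self.psm_labels.items():
                fh.write(f"{sid}\t{'correct' if ok else 'incorrect'}\n")


def _random_aa(rng: np.random.Generator, n: int, alphabet: str = AA_ALPHABET) -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list(NT_ALPHABET))[rng.integers(0, 4, n)])


def generate_proteome(config: SimulationConfig) -> list[SequenceEntry]:
    """Random ground-truth proteome over the 20 standard residues.

    Lengths are normal(mean, sd) rounded and floored at
    ``min_protein_length``; every protein starts with methionine.
    """
    rng = config.rng(_STREAM_PROTEOME)
    entries = []
    for i in range(config.n_proteins):
        length = max(
            config.min_protein_length,
            int(round(rng.normal(config.protein_length_mean, config.protein_length_sd))),
        )
        seq = "M" + _random_aa(rng, length - 1)
        entries.append(
            SequenceEntry(
                accession=f"PROT_{i + 1:05d}",
                sequence=seq,
                description="synthetic ground-truth protein",
                origin=SSTDB,
            )
        )
    return entries


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS with uniformly random synonymous codons (standard genetic code)."""
    codons = []
    for aa in protein:
        try:
            options = CODONS_BY_AA[aa]
        except KeyError:
            raise ValueError(f"residue {aa!r} has no codon in the standard code") from None
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def generate_transcripts(
    proteome: Sequence[SequenceEntry],
    config: SimulationConfig,
) -> tuple[list[SequenceEntry], list[TranscriptTruth]]:
    """Transcripts embedding each protein plus non-coding transcripts.

    Each coding transcript carries the reverse-translated CDS flanked by
    random UTR with in-frame stop codons at the CDS boundaries (the leading
    stop is present only when there is a 5' UTR), so stop-to-stop ORF
    extraction recovers the protein verbatim. The strand of embedding is
    random; coordinates are recorded 0-based half-open on the forward
    strand, with negative frames counted from the reverse complement's
    first base.
    """
    if not proteome and config.n_noncoding_transcripts == 0:
        raise ValueError("nothing to generate: empty proteome and no non-coding transcripts")
    rng = config.rng(_STREAM_TRANSCRIPTS)
    lo, hi = config.utr_length_range
    transcripts = []
    truth = []
    for i, prot in enumerate(proteome):
        cds = reverse_translate(prot.sequence, rng)
        utr5 = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        utr3 = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        stop5 = STOP_CODONS[rng.integers(0, 3)] if utr5 else ""
        stop3 = STOP_CODONS[rng.integers(0, 3)]
        construct = utr5 + stop5 + cds + stop3 + utr3
        cds_start = len(utr5) + len(stop5)
        tid = f"TRX_{i + 1:05d}"
        reverse = bool(rng.integers(0, 2))
        if reverse:
            seq = str(Seq(construct).reverse_complement())
            L = len(seq)
            start = L - (cds_start + len(cds))
            end = L - cds_start
            frame = -((cds_start % 3) + 1)
        else:
            seq = construct
            start = cds_start
            end = cds_start + len(cds)
            frame = (cds_start % 3) + 1
        transcripts.append(
            SequenceEntry(accession=tid, sequence=seq, description="synthetic coding transcript")
        )
        truth.append(TranscriptTruth(tid, prot.accession, frame, start, end))
    nlo, nhi = config.noncoding_length_range
    for j in range(config.n_noncoding_transcripts):
        tid = f"TRX_NC_{j + 1:05d}"
        seq = _random_nt(rng, int(rng.integers(nlo, nhi + 1)))
        transcripts.append(
            SequenceEntry(accession=tid, sequence=seq, description="synthetic non-coding transcript")
        )
        truth.append(TranscriptTruth(tid, None, None, None, None))
    return transcripts, truth


def generate_orthologue_db(
    proteome: Sequence[SequenceEntry],
    config: SimulationConfig,
    alphabet: str = AA_ALPHABET,
) -> tuple[list[SequenceEntry], dict[str, str]]:
    """Divergent orthologue database with a recorded truth pairing.

    A random ``orthologue_fraction`` of proteins get an orthologue copy in
    which each residue is, with probability ``orthologue_divergence``,
    redrawn uniformly from the alphabet (so divergence 1 leaves an expected
    identity of 1/len(alphabet)). Unrelated random entries are appended so
    they make up ``unrelated_fraction`` of the database.
    """
    rng = config.rng(_STREAM_ORTHOLOGUES)
    n_orth = int(round(config.orthologue_fraction * len(proteome)))
    chosen_idx = sorted(rng.choice(len(proteome), size=n_orth, replace=False)) if n_orth else []
    entries = []
    orthologue_map: dict[str, str] = {}
    letters = np.asarray(list(alphabet))
    for k, idx in enumerate(chosen_idx):
        src = proteome[idx]
        seq = np.asarray(list(src.sequence))
        hit = rng.random(len(seq)) < config.orthologue_divergence
        if hit.any():
            seq[hit] = letters[rng.integers(0, len(letters), int(hit.sum()))]
        acc = f"VPDB_{k + 1:05d}"
        entries.append(
            SequenceEntry(
                accession=acc,
                sequence="".join(seq),
                description=f"synthetic orthologue of {src.accession}",
                origin=VPDB,
            )
        )
        orthologue_map[acc] = src.accession
    if config.unrelated_fraction > 0 and n_orth > 0:
        n_unrelated = int(round(n_orth * config.unrelated_fraction / (1 - config.unrelated_fraction)))
    elif config.unrelated_fraction > 0:
        n_unrelated = max(1, int(round(config.unrelated_fraction * len(proteome))))
    else:
        n_unrelated = 0
    for j in range(n_unrelated):
        length = max(
            config.min_protein_length,
            int(round(rng.normal(config.protein_length_mean, config.protein_length_sd))),
        )
        entries.append(
            SequenceEntry(
                accession=f"VPDB_U{j + 1:05d}",
                sequence="M" + _random_aa(rng, length - 1, alphabet),
                description="synthetic unrelated orthologue-database entry",
                origin=VPDB,
            )
        )
    return entries, orthologue_map


def generate_contaminants(config: SimulationConfig) -> list[SequenceEntry]:
    """Random contaminant proteins (defaults to a 260-entry list)."""
    rng = config.rng(_STREAM_CONTAMINANTS)
    return [
        SequenceEntry(
            accession=f"CONT_{i + 1:04d}",
            sequence="M" + _random_aa(rng, config.contaminant_length - 1),
            description="synthetic contaminant",
            origin=CONTAMINANT,
        )
        for i in range(config.n_contaminants)
    ]


def generate_psms(
    target_peptides: Sequence[tuple[str, tuple[str, ...]]],
    decoy_peptides: Sequence[tuple[str, tuple[str, ...]]],
    config: SimulationConfig,
) -> tuple[list[PsmRow], dict[str, bool]]:
    """Synthetic PSM rows with per-spectrum correctness labels.

    ``target_peptides`` and ``decoy_peptides`` are pools of
    ``(peptide_sequence, matched_accessions)``: the target pool holds true
    (ground-truth) tryptic peptides, the decoy pool peptides of reversed
    entries. A fraction ``p_correct`` of spectra draw a true target peptide
    and a score from the correct distribution; the rest draw a random
    target or decoy peptide (equal odds) and an incorrect-distribution
    score.
    """
    if not target_peptides:
        raise ValueError("target peptide pool is empty")
    if not decoy_peptides:
        raise ValueError("decoy peptide pool is empty")
    rng = config.rng(_STREAM_PSMS)
    rows = []
    labels: dict[str, bool] = {}
    width = max(6, len(str(config.n_spectra)))
    for i in range(config.n_spectra):
        sid = f"spec_{i + 1:0{width}d}"
        correct = bool(rng.random() < config.p_correct)
        if correct:
            pep, accs = target_peptides[rng.integers(0, len(target_peptides))]
            score = rng.normal(config.correct_score_mean, config.correct_score_sd)
        else:
            if rng.random() < 0.5:
                pep, accs = target_peptides[rng.integers(0, len(target_peptides))]
            else:
                pep, accs = decoy_peptides[rng.integers(0, len(decoy_peptides))]
            score = rng.normal(config.incorrect_score_mean, config.incorrect_score_sd)
        rows.append(PsmRow(sid, pep, "", float(score), tuple(accs)))
        labels[sid] = correct
    return rows, labels


def write_psm_rows(rows: Sequence[PsmRow], path: str | Path) -> None:
    """Write synthetic PSM rows in the PSM-TSV dialect."""
    with open(path, "w") as fh:
        fh.write("spectrum_id\tpeptide\tmods\tscore\taccessions\n")
        for r in rows:
            fh.write(
                f"{r.spectrum_id}\t{r.peptide}\t{r.mods}\t{r.score:.6f}\t"
                f"{';'.join(r.accessions)}\n"
            )


def generate_blast_hits(
    query_truth: dict[str, str],
    config: SimulationConfig,
    annotatable_fraction: float = 0.8,
) -> list[BlastHit]:
    """Fabricate a plausible BLAST best-hit table for SSTDB entries.

    ``query_truth`` maps SSTDB accession -> ground-truth protein id; a
    random ``annotatable_fraction`` of queries get a hit to a
    Swissprot-style subject of a random species, with a log-uniform e-value
    in [1e-30, 1e-2] and a bit score decreasing in the e-value.
    """
    rng = config.rng(_STREAM_BLAST)
    hits = []
    for q in sorted(query_truth):
        if rng.random() > annotatable_fraction:
            continue
        species = BLAST_SPECIES[rng.integers(0, len(BLAST_SPECIES))]
        prot = query_truth[q]
        subject = f"sp|S{zlib.crc32(prot.encode()) % 99999:05d}|{prot}_{species}"
        e = 10.0 ** rng.uniform(-30, -2)
        bit = 40.0 - 1.8 * np.log10(e) + rng.normal(0, 2)
        hits.append(BlastHit(query=q, subject=subject, e_value=float(e), bit_score=float(bit)))
    return hits
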