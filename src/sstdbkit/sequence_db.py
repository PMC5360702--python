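"""Search-space construction: six-frame translation, decoys, concatenation.

A shotgun proteomics search against a non-model organism uses a species-
specific transcriptome database (SSTDB): every assembled transcript is
translated in all six reading frames, split at stop codons, and fragments
above a minimum length are kept as candidate protein sequences. These are
concatenated with a cross-species orthologue database (VPDB) and known
mass-spectrometry contaminants, and each target entry gets a reversed decoy
so false-match rates can be estimated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio import SeqIO

# Database-origin labels used throughout the pipeline.
SSTDB = "SSTDB"
VPDB = "VPDB"
CONTAMINANT = "CONTAMINANT"

DECOY_PREFIX = "REV_"
CONTAMINANT_PREFIX = "CON_"

_NT_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Standard genetic code; codons containing N (or any non-ACGT symbol)
# translate to X rather than being resolved ambiguously.
_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_ORIGIN_TAGS = {SSTDB: "SSTDB", VPDB: "VPDB", CONTAMINANT: "CON"}
_TAG_ORIGINS = {v: k for k, v in _ORIGIN_TAGS.items()}


@dataclass
class SequenceEntry:
    """One FASTA record with provenance.

    ``origin`` is one of SSTDB / VPDB / CONTAMINANT; ``source_transcript``
    (SSTDB entries only) records the transcript id, reading frame in
    {+1,+2,+3,-1,-2,-3} and the 0-based half-open nucleotide interval on the
    forward strand that the entry was translated from.
    """

    accession: str
    sequence: str
    description: str = ""
    origin: str = SSTDB
    is_decoy: bool = False
    source_transcript: Optional[tuple[str, int, int, int]] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Orf:
    """A stop-free translated fragment of one transcript reading frame.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand, so ``end - start == 3 * len(aa_sequence)`` regardless of
    strand.
    """

    transcript_id: str
    frame: int
    aa_sequence: str
    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start != 3 * len(self.aa_sequence):
            raise ValueError(
                f"ORF coordinates span {self.end - self.start} nt but encode "
                f"{len(self.aa_sequence)} residues"
            )


def _translate_frame(nt: str, offset: int) -> str:
    """Translate one frame; codons with N (or other non-ACGT) become X."""
    aas = []
    for i in range(offset, len(nt) - 2, 3):
        aas.append(_CODON_TO_AA.get(nt[i : i + 3], "X"))
    return "".join(aas)


def six_frame_translate(
    transcript: SequenceEntry | str,
    min_len: int = 60,
    transcript_id: str = "",
) -> list[Orf]:
    """Translate a transcript in all six frames and extract ORFs.

    ORFs are stop-to-stop fragments (no Met-start requirement, matching the
    default of sixpack-style translators); codons containing N translate to
    X, which does not split a fragment. Fragments are kept only when
    *strictly longer* than ``min_len`` residues. Trailing partial codons are
    ignored.

    Parameters
    ----------
    transcript : SequenceEntry or str
        Nucleotide sequence over {A, C, G, T, N} (case-insensitive).
    min_len : int
        Length threshold in residues; fragments of exactly ``min_len``
        residues are excluded.
    transcript_id : str
        Identifier recorded on the ORFs when a bare string is passed.
    """
    if isinstance(transcript, SequenceEntry):
        seq = transcript.sequence
        tid = transcript.accession
    else:
        seq = transcript
        tid = transcript_id
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = seq.upper()
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValueError(
            f"transcript {tid or '<anonymous>'} contains non-nucleotide "
            f"symbols: {sorted(bad)}"
        )

    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    orfs: list[Orf] = []
    for frame in (1, 2, 3, -1, -2, -3):
        strand_seq = seq if frame > 0 else rc
        offset = abs(frame) - 1
        aa = _translate_frame(strand_seq, offset)
        # Split at stop codons, keeping residue offsets of each fragment.
        pos = 0
        for fragment in aa.split("*"):
            if len(fragment) > min_len:
                nt_lo = offset + 3 * pos
                nt_hi = offset + 3 * (pos + len(fragment))
                if frame > 0:
                    start, end = nt_lo, nt_hi
                else:
                    start, end = L - nt_hi, L - nt_lo
                orfs.append(Orf(tid, frame, fragment, start, end))
            pos += len(fragment) + 1  # +1 skips the stop codon
    return orfs


def orfs_to_entries(orfs: Iterable[Orf], description: str = "") -> list[SequenceEntry]:
    """Turn ORFs into SSTDB entries with frame/coordinate provenance."""
    entries = []
    counter: dict[str, int] = {}
    for orf in orfs:
        n = counter.get(orf.transcript_id, 0) + 1
        counter[orf.transcript_id] = n
        entries.append(
            SequenceEntry(
                accession=f"{orf.transcript_id}.f{orf.frame:+d}.orf{n}",
                sequence=orf.aa_sequence,
                description=description,
                origin=SSTDB,
                source_transcript=(orf.transcript_id, orf.frame, orf.start, orf.end),
            )
        )
    return entries


def make_decoys(entries: Sequence[SequenceEntry]) -> list[SequenceEntry]:
    """Reversed-sequence decoy for every target entry.

    One decoy per target: the full amino-acid sequence reversed, accession
    prefixed with ``REV_``, origin preserved. An empty input yields an empty
    output.
    """
    decoys = []
    for e in entries:
        decoys.append(
            replace(
                e,
                accession=DECOY_PREFIX + e.accession,
                sequence=e.sequence[::-1],
                is_decoy=True,
            )
        )
    return decoys


@dataclass
class SearchDatabase:
    """A concatenated target-decoy search space with per-origin counts."""

    entries: list[SequenceEntry]
    by_accession: dict[str, SequenceEntry] = field(init=False, repr=False)

    def __post_init__(self):
        self.by_accession = {}
        for e in self.entries:
            if e.accession in self.by_accession:
                raise ValueError(f"duplicate accession in database: {e.accession!r}")
            self.by_accession[e.accession] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, accession: str) -> SequenceEntry:
        return self.by_accession[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self.by_accession

    def counts(self) -> dict:
        out = {"forward": {}, "decoy": {}}
        for e in self.entries:
            side = "decoy" if e.is_decoy else "forward"
            out[side][e.origin] = out[side].get(e.origin, 0) + 1
        out["n_forward"] = sum(out["forward"].values())
        out["n_decoy"] = sum(out["decoy"].values())
        out["n_total"] = len(self.entries)
        return out


def concatenate_dbs(
    sstdb: Sequence[SequenceEntry],
    vpdb: Sequence[SequenceEntry] = (),
    contaminants: Sequence[SequenceEntry] = (),
    with_decoys: bool = True,
) -> SearchDatabase:
    """Concatenate SSTDB + orthologue + contaminant entries, adding decoys.

    Contaminant accessions receive the ``CON_`` prefix; every target entry
    contributes one reversed decoy when ``with_decoys`` is set. A duplicate
    accession after prefixing raises ``ValueError`` naming it.
    """
    targets: list[SequenceEntry] = []
    for e in sstdb:
        targets.append(replace(e, origin=SSTDB))
    for e in vpdb:
        targets.append(replace(e, origin=VPDB))
    for e in contaminants:
        acc = e.accession
        if not acc.startswith(CONTAMINANT_PREFIX):
            acc = CONTAMINANT_PREFIX + acc
        targets.append(replace(e, accession=acc, origin=CONTAMINANT))
    for t in targets:
        _validate_protein(t)
    entries = list(targets)
    if with_decoys:
        entries.extend(make_decoys(targets))
    return SearchDatabase(entries)


def _validate_protein(e: SequenceEntry) -> None:
    bad = set(e.sequence) - _AA_ALPHABET - {"X"}
    if bad:
        raise ValueError(
            f"entry {e.accession!r} contains invalid residues: {sorted(bad)}"
        )


# ---------------------------------------------------------------------------
# FASTA I/O with provenance headers
#
# Header dialect:  >ACC description [origin=SSTDB|VPDB|CON frame=+2 loc=12:195]
# The decoy prefix REV_ marks decoys; frame/loc appear on SSTDB entries only.
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"\[origin=(\w+)(?:\s+src=(\S+)\s+frame=([+-]\d)\s+loc=(\d+):(\d+))?\]\s*$")


def _format_header(e: SequenceEntry) -> str:
    tags = f"[origin={_ORIGIN_TAGS[e.origin]}"
    if e.source_transcript is not None:
        tid, frame, start, end = e.source_transcript
        tags += f" src={tid} frame={frame:+d} loc={start}:{end}"
    tags += "]"
    desc = f"{e.description} {tags}" if e.description else tags
    return f"{e.accession} {desc}"


def write_fasta(entries: Iterable[SequenceEntry], path: str | Path, width: int = 60) -> None:
    """Write entries as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{_format_header(e)}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


def read_fasta(path: str | Path, default_origin: str = SSTDB) -> list[SequenceEntry]:
    """Read FASTA, recovering provenance from the header dialect.

    Plain headers (no ``[origin=...]`` tag) get ``default_origin`` and are
    treated as targets unless the accession carries the decoy prefix.
    """
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        origin = default_origin
        source = None
        m = _TAG_RE.search(desc)
        if m:
            origin = _TAG_ORIGINS[m.group(1)]
            if m.group(2) is not None:
                source = (m.group(2), int(m.group(3)), int(m.group(4)), int(m.group(5)))
            desc = desc[: m.start()].strip()
        entries.append(
            SequenceEntry(
                accession=rec.id,
                sequence=str(rec.seq),
                description=desc,
                origin=origin,
                is_decoy=rec.id.startswith(DECOY_PREFIX),
                source_transcript=source,
            )
        )
    return entries
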