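"""Annotation transfer from BLAST hits and species/e-value summaries.

Six-frame translated entries carry no functional information, so each is
searched (blastp) against a curated protein database and the description of
the best hit is transferred when its e-value is at most a threshold
(default 1e-4). Best-hit e-values are additionally binned into the
categories <1E-20, 1E-20..1E-10, 1E-10..1E-6 and >1E-6 (boundary values
fall in the bin where they are the lower edge, matching strict '<' bounds),
and a per-species tally with cumulative percentages summarizes where the
transferred annotation comes from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from sstdbkit.sequence_db import SequenceEntry

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

E_CATEGORIES = ("<1E-20", "1E-20..1E-10", "1E-10..1E-6", ">1E-6", "no_hit")


@dataclass(frozen=True)
class BlastHit:
    query: str
    subject: str
    e_value: float
    bit_score: float
    subject_description: str = ""
    subject_species: str = ""

    def __post_init__(self):
        if not (self.e_value >= 0):  # also rejects NaN
            raise ValueError(f"e-value must be finite and >= 0, got {self.e_value}")


@dataclass(frozen=True)
class AnnotationRecord:
    accession: str
    annotated: bool
    description: str = ""
    e_category: str = "no_hit"
    best_hit: Optional[BlastHit] = None


def _species_from_subject(sseqid: str) -> str:
    """Species mnemonic from a Swissprot-style id ``sp|ACC|GENE_SPECIES``."""
    name = sseqid.split("|")[-1]
    if "_" in name:
        return name.rsplit("_", 1)[1]
    return ""


def parse_blast_tabular(
    path: str | Path,
    subject_info: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[BlastHit]:
    """Parse 12-column tabular (outfmt 6) BLAST output.

    ``subject_info`` optionally maps subject accession to
    ``(description, species)``; otherwise the species is taken from a
    Swissprot-style subject id when possible. Comment lines (#) are
    ignored; a malformed line raises ``ValueError`` with its line number.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                e_value = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            subject = fields[1]
            if subject_info and subject in subject_info:
                desc, species = subject_info[subject]
            else:
                desc, species = "", _species_from_subject(subject)
            hits.append(
                BlastHit(
                    query=fields[0],
                    subject=subject,
                    e_value=e_value,
                    bit_score=bit_score,
                    subject_description=desc,
                    subject_species=species,
                )
            )
    return hits


def write_blast_tabular(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (alignment fields zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t100.00\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.e_value:.2e}\t{h.bit_score:.1f}\n"
            )


def best_hits(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    """Per-query best hit: lowest e-value, ties by higher bit score, then
    lexicographically smallest subject accession."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None or (h.e_value, -h.bit_score, h.subject) < (
            cur.e_value,
            -cur.bit_score,
            cur.subject,
        ):
            best[h.query] = h
    return best


def e_value_category(e: float) -> str:
    """Bin an e-value; boundaries belong to the bin they open.

    e < 1e-20 -> "<1E-20"; 1e-20 <= e < 1e-10 -> "1E-20..1E-10";
    1e-10 <= e < 1e-6 -> "1E-10..1E-6"; e >= 1e-6 -> ">1E-6".
    """
    if e < 1e-20:
        return "<1E-20"
    if e < 1e-10:
        return "1E-20..1E-10"
    if e < 1e-6:
        return "1E-10..1E-6"
    return ">1E-6"


def transfer_annotation(
    entries: Sequence[SequenceEntry],
    hits: Iterable[BlastHit],
    threshold: float = 1e-4,
) -> tuple[list[AnnotationRecord], list[SequenceEntry]]:
    """Transfer best-hit descriptions onto entries at the e-value threshold.

    An entry is annotated iff its best hit has e-value <= ``threshold``
    (default 1e-4); the hit's description (or subject id) is appended to the
    entry's description line. Returns the annotation records and the
    (possibly extended) entries. Hits referencing unknown queries are
    skipped with a warning.
    """
    if threshold <= 0:
        raise ValueError("e-value threshold must be positive")
    known = {e.accession for e in entries}
    hits = list(hits)
    unknown = sorted({h.query for h in hits} - known)
    if unknown:
        warnings.warn(
            f"{len(unknown)} BLAST hit query accession(s) not in the entry "
            f"set (first: {unknown[0]!r}); skipped"
        )
        hits = [h for h in hits if h.query in known]
    best = best_hits(hits)

    records = []
    annotated_entries = []
    for entry in entries:
        hit = best.get(entry.accession)
        if hit is None:
            records.append(AnnotationRecord(entry.accession, annotated=False))
            annotated_entries.append(entry)
            continue
        category = e_value_category(hit.e_value)
        if hit.e_value <= threshold:
            transferred = hit.subject_description or hit.subject
            new_desc = (
                f"{entry.description} | similar to {transferred}"
                if entry.description
                else f"similar to {transferred}"
            )
            records.append(
                AnnotationRecord(
                    entry.accession,
                    annotated=True,
                    description=transferred,
                    e_category=category,
                    best_hit=hit,
                )
            )
            annotated_entries.append(replace(entry, description=new_desc))
        else:
            records.append(
                AnnotationRecord(
                    entry.accession,
                    annotated=False,
                    e_category=category,
                    best_hit=hit,
                )
            )
            annotated_entries.append(entry)
    return records, annotated_entries


def summarize_species(
    records: Sequence[AnnotationRecord],
    vpdb_species: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-species tally of best-hit e-value categories plus direct
    orthologue-database identifications.

    ``vpdb_species`` maps species -> count of identifications made directly
    in the orthologue database (no BLAST transfer involved). Rows are sorted
    by grand total descending (ties by species name) and carry a cumulative
    percentage over the grand total.
    """
    tally: dict[str, dict[str, int]] = {}

    def row(species: str) -> dict[str, int]:
        return tally.setdefault(
            species, {c: 0 for c in E_CATEGORIES[:-1]} | {"viridi_entry": 0}
        )

    for r in records:
        if r.best_hit is None:
            continue
        species = r.best_hit.subject_species or "NA"
        row(species)[r.e_category] += 1
    for species, n in (vpdb_species or {}).items():
        row(species)["viridi_entry"] += n

    df = pd.DataFrame.from_dict(tally, orient="index").rename_axis("species").reset_index()
    if df.empty:
        return pd.DataFrame(
            columns=["species", *E_CATEGORIES[:-1], "viridi_entry", "total",
                     "percent", "cumulative_percent"]
        )
    df["total"] = df.drop(columns="species").sum(axis=1)
    df = df.sort_values(
        ["total", "species"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    grand = int(df["total"].sum())
    df["percent"] = (100.0 * df["total"] / grand).round(2)
    df["cumulative_percent"] = (100.0 * df["total"].cumsum() / grand).round(2)
    return df
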