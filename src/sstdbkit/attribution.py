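"""Database-origin attribution: conflicts, classification, gain report.

The headline question of a proteogenomics search against a combined
species-specific (SSTDB) + orthologue (VPDB) database is how much each
database contributes. Every accepted PSM, unique peptide and protein
cluster is classified as matched in *both* databases, *only* the SSTDB, or
*only* the VPDB, and the peptide-level enrichment ratio

    (sstdb_only + both) / (vpdb_only + both)

measures how many more peptide sequences the transcriptome database yields
over searching the orthologue database alone.

Conflicts: when one spectrum produces two or more equal-scoring hits with
genuinely different peptide sequences (different amino-acid order — typical
for permuted N-terminal residues of isobaric peptides), neither assignment
can be trusted and the spectrum is removed from all origin counts. Pure
Leu/Ile variants score identically because the residues are isobaric; they
are one identification, not a conflict, and are collapsed via the I/L key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from sstdbkit.protein_inference import ProteinCluster
from sstdbkit.psm_validation import ACCEPTED, CONFLICT, PSM, REJECTED
from sstdbkit.sequence_db import CONTAMINANT, SSTDB, VPDB

BOTH = "both"
SSTDB_ONLY = "sstdb_only"
VPDB_ONLY = "vpdb_only"
CONFLICT_CATEGORY = "conflict"

# Relative score tolerance under which two hits count as "exactly the same
# score" on a floating-point export.
SCORE_REL_TOL = 1e-6


def _same_score(a: float, b: float) -> bool:
    scale = max(abs(a), abs(b), 1e-300)
    return abs(a - b) <= SCORE_REL_TOL * scale


def detect_conflicts(psms: Sequence[PSM]) -> list[PSM]:
    """Mark conflicting spectra; keep one representative hit per spectrum.

    Within each spectrum the top-scoring hits (equal within a relative
    tolerance) are examined: if they name more than one distinct
    I/L-collapsed sequence, the whole spectrum is a conflict and every one
    of its PSMs is marked ``conflict``. Otherwise the equal-top hits are the
    same identification; the lexicographically first is kept and the other
    rows (including lower-scoring hits) are marked ``rejected``.
    Returns the input list (statuses mutated) for chaining.
    """
    by_spectrum: dict[str, list[PSM]] = {}
    for p in psms:
        by_spectrum.setdefault(p.spectrum_id, []).append(p)
    for hits in by_spectrum.values():
        top_score = max(h.score for h in hits)
        winners = [h for h in hits if _same_score(h.score, top_score)]
        il_keys = {w.peptide.il_key for w in winners}
        if len(il_keys) > 1:
            for h in hits:
                h.status = CONFLICT
        else:
            keep = min(
                winners,
                key=lambda h: (h.peptide.sequence, h.peptide.mod_string, h.matched_entries),
            )
            for h in hits:
                if h is not keep:
                    h.status = REJECTED
    return list(psms)


def classify_origin(origins: Iterable[str]) -> str:
    """Classify a set of matched-entry origins as both/sstdb_only/vpdb_only.

    Contaminant matches are ignored; an item matching nothing but
    contaminants (or nothing at all) cannot be classified and raises
    ``ValueError`` — such items are excluded upstream.
    """
    relevant = {o for o in origins if o != CONTAMINANT}
    if not relevant:
        raise ValueError("item has no non-contaminant match to classify")
    if relevant == {SSTDB}:
        return SSTDB_ONLY
    if relevant == {VPDB}:
        return VPDB_ONLY
    return BOTH


def _is_contaminant_only(origins: Iterable[str]) -> bool:
    s = set(origins)
    return bool(s) and s == {CONTAMINANT}


@dataclass
class LevelCounts:
    """Category counts at one level with percentages against a total."""

    total: int
    counts: dict[str, int]
    percent_base: Optional[int] = None  # defaults to total

    def percentages(self) -> dict[str, float]:
        base = self.percent_base if self.percent_base is not None else self.total
        return {k: round(100.0 * v / base, 2) for k, v in self.counts.items()}


@dataclass
class AttributionReport:
    """Counts, percentages and enrichment ratio per level.

    Levels: ``psm`` (accepted spectra plus conflicting spectra), ``peptide``
    (unique I/L-collapsed sequences of accepted PSMs) and ``cluster``.
    The enrichment ratio compares peptide yield with and without the
    species-specific database:
    ``(sstdb_only + both) / (vpdb_only + both)`` at peptide level.
    Contaminant-only identifications are tallied separately and excluded
    from the origin categories.
    """

    psm: LevelCounts
    peptide: LevelCounts
    cluster: Optional[LevelCounts] = None
    psm_conflicts_by_origin: dict[str, int] = field(default_factory=dict)
    n_contaminant_only: int = 0

    @property
    def enrichment_ratio(self) -> Optional[float]:
        c = self.peptide.counts
        num = c.get(SSTDB_ONLY, 0) + c.get(BOTH, 0)
        den = c.get(VPDB_ONLY, 0) + c.get(BOTH, 0)
        if den == 0:
            return None  # undefined without any orthologue-database evidence
        return num / den

    def to_dict(self) -> dict:
        ratio = self.enrichment_ratio
        out = {
            "psm": {
                "total": self.psm.total,
                "counts": dict(self.psm.counts),
                "percent": self.psm.percentages(),
            },
            "peptide": {
                "total": self.peptide.total,
                "counts": dict(self.peptide.counts),
                "percent": self.peptide.percentages(),
            },
            "psm_conflicts_by_origin": dict(self.psm_conflicts_by_origin),
            "n_contaminant_only": self.n_contaminant_only,
            "enrichment_ratio": None if ratio is None else round(ratio, 2),
            "enrichment_ratio_display": "undefined" if ratio is None else f"{ratio:.1f}",
        }
        if self.cluster is not None:
            out["cluster"] = {
                "total": self.cluster.total,
                "counts": dict(self.cluster.counts),
                "percent": self.cluster.percentages(),
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_table(self) -> str:
        """Human-readable two-column table of PSM and peptide attribution."""
        rows = [
            ("", "Assigned PSM", "Unique peptides (conflicts removed)"),
            (
                "Total assignments (%)",
                f"{self.psm.total:,} (100%)",
                f"{self.peptide.total:,} (100%)",
            ),
        ]
        pp, qp = self.psm.percentages(), self.peptide.percentages()
        labels = [
            (BOTH, "Assigned with VPDB and SSTDB - no conflicts (%)"),
            (SSTDB_ONLY, "Assigned ONLY with SSTDB - no conflicts (%)"),
            (VPDB_ONLY, "Assigned ONLY with VPDB - no conflicts (%)"),
            (CONFLICT_CATEGORY, "Conflicting (%)"),
        ]
        for key, label in labels:
            rows.append(
                (
                    label,
                    f"{self.psm.counts.get(key, 0):,} ({pp.get(key, 0):.2f}%)",
                    f"{self.peptide.counts.get(key, 0):,} ({qp.get(key, 0):.2f}%)"
                    if key != CONFLICT_CATEGORY
                    else "",
                )
            )
        widths = [max(len(r[i]) for r in rows) for i in range(3)]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip()
            for r in rows
        )

    @classmethod
    def from_counts(
        cls,
        psm_counts: Mapping[str, int],
        peptide_counts: Mapping[str, int],
        cluster_counts: Optional[Mapping[str, int]] = None,
    ) -> "AttributionReport":
        """Build a report directly from category counts (worked examples).

        Peptide-level percentages for the conflict category, when present,
        are computed against the PSM total, matching how conflict rows are
        reported alongside per-spectrum counts.
        """
        psm = LevelCounts(total=sum(psm_counts.values()), counts=dict(psm_counts))
        peptide = LevelCounts(
            total=sum(peptide_counts.values()), counts=dict(peptide_counts)
        )
        cluster = None
        if cluster_counts is not None:
            cluster = LevelCounts(
                total=sum(cluster_counts.values()), counts=dict(cluster_counts)
            )
        return cls(psm=psm, peptide=peptide, cluster=cluster)


def build_report(
    psms: Sequence[PSM],
    clusters: Optional[Sequence[ProteinCluster]] = None,
) -> AttributionReport:
    """Attribution report over validated PSMs (and optionally clusters).

    PSM level counts one row per accepted spectrum plus one per conflicting
    spectrum; peptide level pools the accepted PSMs of each unique
    I/L-collapsed sequence; cluster level uses member origins. Requires at
    least one accepted or conflicting PSM.
    """
    accepted = [p for p in psms if p.status == ACCEPTED and not p.is_decoy]
    conflict_spectra: dict[str, set[str]] = {}
    for p in psms:
        if p.status == CONFLICT:
            conflict_spectra.setdefault(p.spectrum_id, set()).update(
                o for _, o, _ in p.matched_entries
            )
    if not accepted and not conflict_spectra:
        raise ValueError("no accepted or conflicting PSMs to attribute")

    psm_counts = {BOTH: 0, SSTDB_ONLY: 0, VPDB_ONLY: 0, CONFLICT_CATEGORY: len(conflict_spectra)}
    n_contaminant_only = 0
    for p in accepted:
        if _is_contaminant_only(p.origins):
            n_contaminant_only += 1
            continue
        psm_counts[classify_origin(p.origins)] += 1

    # Conflicting spectra attributed by the pooled origins of their hits.
    conflicts_by_origin = {BOTH: 0, SSTDB_ONLY: 0, VPDB_ONLY: 0}
    for origins in conflict_spectra.values():
        relevant = {o for o in origins if o != CONTAMINANT}
        if relevant:
            conflicts_by_origin[classify_origin(relevant)] += 1

    psm_total = sum(psm_counts.values()) + n_contaminant_only

    # Peptide level: pool origins over all accepted PSMs of each il_key.
    pep_origins: dict[str, set[str]] = {}
    for p in accepted:
        pep_origins.setdefault(p.peptide.il_key, set()).update(p.origins)
    peptide_counts = {BOTH: 0, SSTDB_ONLY: 0, VPDB_ONLY: 0}
    for origins in pep_origins.values():
        if _is_contaminant_only(origins):
            continue
        peptide_counts[classify_origin(origins)] += 1

    report = AttributionReport(
        psm=LevelCounts(total=psm_total, counts=psm_counts),
        peptide=LevelCounts(
            total=sum(peptide_counts.values()), counts=peptide_counts
        ),
        psm_conflicts_by_origin=conflicts_by_origin,
        n_contaminant_only=n_contaminant_only,
    )
    if clusters is not None:
        cl_counts = {BOTH: 0, SSTDB_ONLY: 0, VPDB_ONLY: 0}
        for c in clusters:
            if c.is_decoy or _is_contaminant_only(c.origins):
                continue
            cl_counts[classify_origin(c.origins)] += 1
        report.cluster = LevelCounts(total=sum(cl_counts.values()), counts=cl_counts)
    return report
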