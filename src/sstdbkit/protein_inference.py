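"""Parsimony protein inference: peptide mapping, grouping, cluster FDR.

Shared peptides make individual protein identifications ambiguous, so
proteins are reported as clusters satisfying parsimony:

1. entries with identical peptide evidence are merged (indistinguishable by
   MS/MS alone);
2. an entry whose peptide set is a proper subset of another's is absorbed
   into that entry's group (it explains nothing extra);
3. remaining groups are added greedily in decreasing order of uncovered
   peptide count until every peptide is covered — a standard greedy minimal
   set cover, deterministic with ties broken by representative accession.

Peptide identity is I/L-collapsed throughout. A cluster is a decoy cluster
only when every member is a decoy; cluster FDR is
100 * decoy clusters / target clusters, with contaminant-only clusters
reported separately and excluded from the FDR by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence
import warnings

from sstdbkit.digestion import digest_database
from sstdbkit.psm_validation import FdrEstimate
from sstdbkit.sequence_db import CONTAMINANT, SearchDatabase


@dataclass(frozen=True)
class ProteinCluster:
    """A parsimony group of database entries sharing peptide evidence."""

    cluster_id: int
    member_accessions: tuple[str, ...]
    origins: frozenset[str]
    is_decoy: bool
    peptides: frozenset[str]  # il_key-collapsed peptide identifiers
    representative: str

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)


def map_peptides(
    peptides: Iterable[str],
    database: SearchDatabase | Sequence,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    index: Optional[Mapping[str, set[str]]] = None,
) -> dict[str, set[str]]:
    """Link each peptide (il_key) to every database entry whose digest has it.

    The database is digested with the same settings used for searching;
    matching is on the I/L-collapsed sequence. Peptides matching no entry
    are recorded as orphans with a warning and omitted from the map.
    """
    if index is None:
        entries = database.entries if isinstance(database, SearchDatabase) else database
        index = digest_database(entries, max_missed=max_missed, min_len=min_len, max_len=max_len)
    mapping: dict[str, set[str]] = {}
    orphans = []
    for pep in peptides:
        key = pep.replace("I", "L")
        hits = index.get(key)
        if hits:
            mapping[key] = set(hits)
        else:
            orphans.append(key)
    if orphans:
        warnings.warn(
            f"{len(orphans)} peptide(s) matched no database entry "
            f"(first: {orphans[0]!r})"
        )
    return mapping


def _peptide_sets_by_entry(mapping: Mapping[str, set[str]]) -> dict[str, frozenset[str]]:
    by_entry: dict[str, set[str]] = {}
    for pep, accs in mapping.items():
        for acc in accs:
            by_entry.setdefault(acc, set()).add(pep)
    return {acc: frozenset(peps) for acc, peps in by_entry.items()}


def group_parsimony(
    mapping: Mapping[str, set[str]],
    database: Optional[SearchDatabase] = None,
) -> list[ProteinCluster]:
    """Group entries into parsimony clusters covering all mapped peptides.

    ``mapping`` is peptide il_key -> set of matching accessions (as produced
    by :func:`map_peptides`). Origin and decoy flags are taken from
    ``database`` when given; otherwise origins are empty and decoy status is
    inferred from the ``REV_`` accession prefix.
    """
    if not mapping:
        raise ValueError("cannot group an empty peptide-protein map")
    by_entry = _peptide_sets_by_entry(mapping)

    # Rule 1: merge entries with identical peptide sets.
    groups: dict[frozenset[str], list[str]] = {}
    for acc in sorted(by_entry):
        groups.setdefault(by_entry[acc], []).append(acc)

    # Rule 2: absorb groups whose peptide set is a proper subset of another's.
    # The absorbing group is the smallest strict superset (deterministic by
    # sorted iteration); absorbed members join it without extending its set.
    peptide_sets = sorted(groups, key=lambda s: (-len(s), sorted(s)))
    members: dict[frozenset[str], list[str]] = {s: list(groups[s]) for s in peptide_sets}
    absorbed: set[frozenset[str]] = set()
    for small in reversed(peptide_sets):  # smallest first
        for big in peptide_sets:
            if big is small or big in absorbed:
                continue
            if small < big:
                members[big].extend(members[small])
                absorbed.add(small)
                break
    surviving = [s for s in peptide_sets if s not in absorbed]

    # Rule 3: greedy minimal cover over the surviving groups.
    def representative(accs: Sequence[str]) -> str:
        return min(accs, key=lambda a: (-len(by_entry[a]), a))

    uncovered = set(mapping)
    chosen: list[frozenset[str]] = []
    remaining = set(surviving)
    while uncovered:
        gain = max(len(s & uncovered) for s in remaining)
        tied = [s for s in remaining if len(s & uncovered) == gain]
        best = min(tied, key=lambda s: representative(members[s]))
        chosen.append(best)
        remaining.discard(best)
        uncovered -= best

    clusters = []
    for i, pepset in enumerate(
        sorted(chosen, key=lambda s: representative(members[s])), start=1
    ):
        accs = tuple(sorted(members[pepset]))
        if database is not None:
            origins = frozenset(database[a].origin for a in accs)
            is_decoy = all(database[a].is_decoy for a in accs)
        else:
            origins = frozenset()
            is_decoy = all(a.startswith("REV_") for a in accs)
        clusters.append(
            ProteinCluster(
                cluster_id=i,
                member_accessions=accs,
                origins=origins,
                is_decoy=is_decoy,
                peptides=pepset,
                representative=representative(accs),
            )
        )
    return clusters


def cluster_fdr(
    clusters: Sequence[ProteinCluster],
    exclude_contaminants: bool = True,
) -> FdrEstimate:
    """Protein-cluster FDR: 100 * decoy clusters / target clusters.

    Contaminant-only clusters are excluded from both counts by default and
    reported separately by the pipeline.
    """
    considered = [
        c
        for c in clusters
        if not (exclude_contaminants and c.origins and c.origins == {CONTAMINANT})
    ]
    n_decoy = sum(1 for c in considered if c.is_decoy)
    n_target = len(considered) - n_decoy
    return FdrEstimate("protein_cluster", n_decoy, n_target)
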