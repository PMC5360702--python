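"""In-silico tryptic digestion, modifications, and monoisotopic masses.

Search settings mirror a typical Orbitrap/Mascot configuration: trypsin
(cleavage after K/R except before P) with up to 2 missed cleavages, fixed
carbamidomethylation of cysteine, and variable deamidation (N/Q),
Gln->pyro-Glu (N-terminal Q) and oxidation (M). Precursor matching uses a
ppm tolerance; the fragment-ion tolerance (0.6 Da) is carried in pipeline
configuration for completeness but is inert because spectra are never
simulated.

Peptides carry two identity keys used throughout matching and conflict
detection: ``il_key`` (sequence with I replaced by L — leucine and
isoleucine are isobaric and indistinguishable by MS) and
``composition_key`` (sorted residue multiset, invariant under permutation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from pyteomics import mass as _pymass
from pyteomics import parser as _pyparser

WATER_MONO = 18.010565  # monoisotopic mass of H2O in Da

RESIDUE_MASSES = dict(_pymass.std_aa_mass)
RESIDUE_MASSES["X"] = 0.0  # unknown residue: mass contribution undefined

# Monoisotopic mass deltas (Da) for the supported modifications.
MODIFICATION_DELTAS = {
    "Carbamidomethyl": 57.02146,
    "Deamidated": 0.98402,
    "Gln->pyro-Glu": -17.02655,
    "Oxidation": 15.99491,
}

FIXED_MODIFICATIONS = (("C", "Carbamidomethyl"),)

# Cleave after K or R except before P (without the expasy WKP/MRP
# exception-to-the-exception).
TRYPSIN_RULE = r"[KR](?!P)"

_VALID_RESIDUES = frozenset(RESIDUE_MASSES) - {"B", "Z", "J", "U", "O"} | {"X"}


@dataclass(frozen=True)
class Peptide:
    """A peptide with modifications and positional provenance.

    ``modifications`` is a tuple of ``(position, name, mass_delta)`` with
    0-based positions in the peptide; fixed carbamidomethylation of every C
    is implicit and applied by :func:`peptide_mass`, not listed here unless
    explicitly enumerated.
    """

    sequence: str
    modifications: tuple[tuple[int, str, float], ...] = ()
    missed_cleavages: int = 0
    start: int = 0  # 0-based offset in the parent sequence
    parent_accession: Optional[str] = None

    @property
    def il_key(self) -> str:
        """Sequence with every I replaced by L (isobaric collapse)."""
        return self.sequence.replace("I", "L")

    @property
    def composition_key(self) -> str:
        """Sorted residue multiset; invariant under any permutation."""
        return "".join(sorted(self.sequence))

    @property
    def mod_string(self) -> str:
        """Canonical text form of the variable modifications."""
        return ";".join(f"{pos}:{name}" for pos, name, _ in self.modifications)

    @property
    def mono_mass(self) -> float:
        return peptide_mass(self)

    def __len__(self) -> int:
        return len(self.sequence)


def _count_missed(pep: str) -> int:
    """Internal uncleaved K/R sites (K/R not followed by P) within a peptide."""
    return sum(
        1
        for i in range(len(pep) - 1)
        if pep[i] in "KR" and pep[i + 1] != "P"
    )


def digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 1,
    max_len: Optional[int] = None,
    parent_accession: Optional[str] = None,
) -> list[Peptide]:
    """Tryptic digest with up to ``max_missed`` missed cleavages.

    Cleaves after K or R except when the next residue is P; emits every
    peptide with 0..``max_missed`` internal missed-cleavage sites whose
    length lies in ``[min_len, max_len]``. Positions are recorded against
    the parent sequence. Peptides are returned sorted by (start, length).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bad = set(sequence) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    peptides = []
    for start, pep in _pyparser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=max_missed
    ):
        if len(pep) < min_len or (max_len is not None and len(pep) > max_len):
            continue
        peptides.append(
            Peptide(
                sequence=pep,
                missed_cleavages=_count_missed(pep),
                start=start,
                parent_accession=parent_accession,
            )
        )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def peptide_mass(p: Peptide | str, fixed: Sequence[tuple[str, str]] = FIXED_MODIFICATIONS) -> float:
    """Monoisotopic mass in Da: water + residues + fixed + variable deltas.

    Fixed modifications (default: carbamidomethyl on every C) are applied to
    each matching residue; variable modifications listed on the peptide are
    added on top.
    """
    if isinstance(p, str):
        p = Peptide(p)
    total = WATER_MONO
    for aa in p.sequence:
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    for residue, name in fixed:
        try:
            delta = MODIFICATION_DELTAS[name]
        except KeyError:
            raise KeyError(f"unknown modification {name!r}") from None
        total += delta * p.sequence.count(residue)
    for _, name, delta in p.modifications:
        if name not in MODIFICATION_DELTAS:
            raise KeyError(f"unknown modification {name!r}")
        total += delta
    return total


def enumerate_modifications(p: Peptide, max_variable: int = 3) -> list[Peptide]:
    """All variable-modification forms of a peptide, unmodified form first.

    Variable modifications: deamidation at N/Q, oxidation at M, and
    Gln->pyro-Glu at an N-terminal Q. At an N-terminal Q, pyro-Glu and
    deamidation are alternatives — never co-applied at the same position.
    At most ``max_variable`` variable modifications per peptide.
    """
    site_options: list[list[tuple[str, float]]] = []
    positions: list[int] = []
    for i, aa in enumerate(p.sequence):
        opts: list[tuple[str, float]] = []
        if aa in "NQ":
            opts.append(("Deamidated", MODIFICATION_DELTAS["Deamidated"]))
        if aa == "Q" and i == 0:
            opts.append(("Gln->pyro-Glu", MODIFICATION_DELTAS["Gln->pyro-Glu"]))
        if aa == "M":
            opts.append(("Oxidation", MODIFICATION_DELTAS["Oxidation"]))
        if opts:
            positions.append(i)
            site_options.append(opts)

    forms = []
    for k in range(0, min(max_variable, len(positions)) + 1):
        for chosen in itertools.combinations(range(len(positions)), k):
            for combo in itertools.product(*(site_options[j] for j in chosen)):
                mods = tuple(
                    (positions[j], name, delta)
                    for j, (name, delta) in zip(chosen, combo)
                )
                forms.append(
                    Peptide(
                        sequence=p.sequence,
                        modifications=mods,
                        missed_cleavages=p.missed_cleavages,
                        start=p.start,
                        parent_accession=p.parent_accession,
                    )
                )
    return forms


def tolerance_match(observed_mass: float, p: Peptide | str, ppm: float = 10.0) -> bool:
    """True iff the observed mass lies within ``ppm`` of the theoretical one."""
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    theoretical = peptide_mass(p)
    if observed_mass <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return abs(observed_mass - theoretical) / theoretical * 1e6 <= ppm


def digest_database(
    entries: Iterable,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> dict[str, set[str]]:
    """Index a database digest: il_key -> set of accessions containing it."""
    index: dict[str, set[str]] = {}
    for e in entries:
        for pep in digest(e.sequence, max_missed=max_missed, min_len=min_len, max_len=max_len):
            index.setdefault(pep.il_key, set()).add(e.accession)
    return index
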