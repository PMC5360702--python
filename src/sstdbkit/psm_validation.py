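"""PSM ingestion, mixture-model posteriors, filtering and decoy FDR.

Peptide-spectrum matches arrive as a tab-separated export (one row per
match). A two-component Gaussian mixture fitted by expectation-maximization
assigns each PSM a posterior probability of being correct — a documented,
simplified stand-in for the PeptideProphet discriminant model: the search
score itself is modeled as a mixture of an incorrect (lower-mean) and a
correct (higher-mean) component, and the posterior is the correct-component
responsibility. PSMs are accepted above a probability threshold (default
0.95) and the false discovery rate is estimated from decoy hits as

    FDR = 100 * n_decoy_accepted / n_target_accepted   [percent]

at the PSM level and at the unique-peptide level (uniqueness on the
I/L-collapsed sequence plus the modification string).

PSM-TSV dialect (tab-separated, header row):
    spectrum_id    peptide    mods    score    accessions
``mods`` is the canonical ``pos:Name;...`` form (may be empty);
``accessions`` is a semicolon-separated list resolved against the
concatenated search database.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm

from sstdbkit.digestion import MODIFICATION_DELTAS, Peptide
from sstdbkit.sequence_db import SearchDatabase

PSM_COLUMNS = ("spectrum_id", "peptide", "mods", "score", "accessions")

# PSM lifecycle states.
PENDING = "pending"
ACCEPTED = "accepted"
REJECTED = "rejected"
CONFLICT = "conflict"


@dataclass
class PSM:
    """One peptide-spectrum match.

    ``matched_entries`` holds ``(accession, origin, is_decoy)`` for every
    database entry the search matched. A PSM whose matches are all decoy is
    a decoy PSM; ``status`` moves from pending to accepted/rejected by the
    probability filter, or to conflict when another equal-scoring hit on the
    same spectrum names a genuinely different peptide.
    """

    spectrum_id: str
    peptide: Peptide
    score: float
    matched_entries: tuple[tuple[str, str, bool], ...]
    posterior: Optional[float] = None
    status: str = PENDING

    def __post_init__(self):
        if not self.matched_entries:
            raise ValueError(f"PSM {self.spectrum_id} has no matched entries")

    @property
    def is_decoy(self) -> bool:
        return all(d for _, _, d in self.matched_entries)

    @property
    def origins(self) -> frozenset[str]:
        return frozenset(o for _, o, _ in self.matched_entries)

    @property
    def peptide_key(self) -> tuple[str, str]:
        """Unique-peptide identity: I/L-collapsed sequence + modifications."""
        return (self.peptide.il_key, self.peptide.mod_string)


@dataclass(frozen=True)
class FdrEstimate:
    """Decoy-based FDR at one level, in percent with two decimals."""

    level: str  # psm | peptide | protein_cluster
    n_decoy: int
    n_target: int

    def __post_init__(self):
        if self.n_target <= 0:
            raise ValueError("FDR undefined: no target identifications")
        if self.n_decoy < 0:
            raise ValueError("decoy count cannot be negative")

    @property
    def fdr(self) -> float:
        return round(100.0 * self.n_decoy / self.n_target, 2)


def _parse_mods(text: str) -> tuple[tuple[int, str, float], ...]:
    if not text:
        return ()
    mods = []
    for part in text.split(";"):
        pos, name = part.split(":", 1)
        if name not in MODIFICATION_DELTAS:
            raise ValueError(f"unknown modification {name!r}")
        mods.append((int(pos), name, MODIFICATION_DELTAS[name]))
    return tuple(mods)


def read_psm_table(path: str | Path, database: SearchDatabase) -> list[PSM]:
    """Read a PSM-TSV file, resolving accessions against the database.

    Multiple rows with the same spectrum id are retained for conflict
    analysis. An unknown accession raises ``KeyError`` naming it; a
    malformed row raises ``ValueError`` with its line number.
    """
    psms: list[PSM] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PSM_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {PSM_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PSM_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(PSM_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            spectrum_id, pep_seq, mods_text, score_text, acc_text = fields
            try:
                score = float(score_text)
                mods = _parse_mods(mods_text)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            matched = []
            for acc in acc_text.split(";"):
                if acc not in database:
                    raise KeyError(
                        f"{path}: line {lineno}: accession {acc!r} not in database"
                    )
                entry = database[acc]
                matched.append((acc, entry.origin, entry.is_decoy))
            psms.append(
                PSM(
                    spectrum_id=spectrum_id,
                    peptide=Peptide(sequence=pep_seq, modifications=mods),
                    score=score,
                    matched_entries=tuple(matched),
                )
            )
    return psms


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    """Write PSMs in the PSM-TSV dialect (deterministic byte output)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for p in psms:
            accs = ";".join(acc for acc, _, _ in p.matched_entries)
            fh.write(
                f"{p.spectrum_id}\t{p.peptide.sequence}\t{p.peptide.mod_string}\t"
                f"{p.score:.6f}\t{accs}\n"
            )


@dataclass
class MixtureFit:
    """Parameters of the two-Gaussian score mixture.

    Component 0 is the incorrect (lower-mean) population, component 1 the
    correct one; ``pi_correct`` is the correct-component mixing proportion.
    ``degenerate`` marks a failed fit (zero variance), in which case
    posteriors are unset and filtering falls back to decoy-only estimation.
    """

    mu_incorrect: float
    mu_correct: float
    sigma_incorrect: float
    sigma_correct: float
    pi_correct: float
    n_iterations: int
    log_likelihood: float
    degenerate: bool = False

    def posterior(self, scores: np.ndarray) -> np.ndarray:
        """Correct-component responsibility for each score."""
        scores = np.asarray(scores, dtype=float)
        lc = np.log(self.pi_correct) + norm.logpdf(scores, self.mu_correct, self.sigma_correct)
        li = np.log1p(-self.pi_correct) + norm.logpdf(scores, self.mu_incorrect, self.sigma_incorrect)
        m = np.maximum(lc, li)
        return np.exp(lc - m) / (np.exp(lc - m) + np.exp(li - m))


_MIN_SIGMA = 1e-8


def fit_mixture(
    scores: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to PSM scores by EM.

    Deterministic initialization: component means at the 25th and 75th score
    percentiles, equal variances (the overall variance), mixing 0.5. EM runs
    until the relative log-likelihood change falls below ``tol`` or
    ``max_iter`` iterations. A degenerate score set (zero spread) cannot
    support a mixture; the fit is returned flagged ``degenerate`` with a
    warning, and downstream filtering uses decoy counts only.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 50:
        raise ValueError(f"need at least 50 scores to fit a mixture, got {x.size}")
    sigma0 = float(np.std(x))
    mu_i, mu_c = float(np.percentile(x, 25)), float(np.percentile(x, 75))
    if sigma0 < _MIN_SIGMA or mu_c - mu_i < _MIN_SIGMA:
        warnings.warn(
            "degenerate score distribution: mixture fit skipped, "
            "falling back to decoy-only filtering"
        )
        return MixtureFit(mu_i, mu_c, max(sigma0, _MIN_SIGMA), max(sigma0, _MIN_SIGMA),
                          0.5, 0, -math.inf, degenerate=True)

    pi = 0.5
    si, sc = sigma0, sigma0
    prev_ll = -math.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step in log space for numerical stability.
        lc = np.log(pi) + norm.logpdf(x, mu_c, sc)
        li = np.log1p(-pi) + norm.logpdf(x, mu_i, si)
        m = np.maximum(lc, li)
        denom = np.exp(lc - m) + np.exp(li - m)
        ll = float(np.sum(m + np.log(denom)))
        r = np.exp(lc - m) / denom  # responsibility of the correct component

        # M-step.
        nc = float(np.sum(r))
        ni = x.size - nc
        if nc < _MIN_SIGMA or ni < _MIN_SIGMA:
            break
        pi = nc / x.size
        mu_c = float(np.sum(r * x) / nc)
        mu_i = float(np.sum((1 - r) * x) / ni)
        sc = math.sqrt(max(float(np.sum(r * (x - mu_c) ** 2) / nc), _MIN_SIGMA**2))
        si = math.sqrt(max(float(np.sum((1 - r) * (x - mu_i) ** 2) / ni), _MIN_SIGMA**2))

        if prev_ll > -math.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll

    # Enforce the labeling convention: correct component has the higher mean.
    if mu_c < mu_i:
        mu_i, mu_c = mu_c, mu_i
        si, sc = sc, si
        pi = 1.0 - pi
    return MixtureFit(mu_i, mu_c, si, sc, pi, n_iter, prev_ll)


def assign_posteriors(psms: Sequence[PSM], fit: Optional[MixtureFit] = None) -> MixtureFit:
    """Fit the score mixture (unless given) and set each PSM's posterior."""
    if fit is None:
        fit = fit_mixture([p.score for p in psms])
    if not fit.degenerate:
        post = fit.posterior(np.array([p.score for p in psms]))
        for p, pr in zip(psms, post):
            p.posterior = float(pr)
    return fit


def filter_psms(
    psms: Sequence[PSM],
    threshold: float = 0.95,
) -> tuple[list[PSM], FdrEstimate, FdrEstimate]:
    """Accept PSMs with posterior above the threshold; estimate decoy FDR.

    Returns ``(accepted, psm_level_fdr, peptide_level_fdr)``. Conflict PSMs
    are never accepted. When posteriors are unset (degenerate mixture), all
    non-conflict PSMs pass and the decoy-based FDR is the only guard.
    Peptide-level counts collapse I/L and keep modification strings
    distinct; a peptide is decoy when every accepted PSM carrying it is a
    decoy match.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("probability threshold must lie strictly in (0, 1)")
    accepted: list[PSM] = []
    for p in psms:
        if p.status == CONFLICT:
            continue
        passed = True if p.posterior is None else p.posterior > threshold
        p.status = ACCEPTED if passed else REJECTED
        if passed:
            accepted.append(p)

    n_decoy = sum(1 for p in accepted if p.is_decoy)
    n_target = len(accepted) - n_decoy
    psm_fdr = FdrEstimate("psm", n_decoy, n_target)

    pep_decoy: dict[tuple[str, str], bool] = {}
    for p in accepted:
        key = p.peptide_key
        pep_decoy[key] = pep_decoy.get(key, True) and p.is_decoy
    nd = sum(1 for d in pep_decoy.values() if d)
    peptide_fdr = FdrEstimate("peptide", nd, len(pep_decoy) - nd)
    return accepted, psm_fdr, peptide_fdr
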