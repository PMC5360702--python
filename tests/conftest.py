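import itertools
import re

import numpy as np
import pytest
from Bio.Seq import Seq

from sstdbkit.pipeline import PipelineConfig, run_pipeline, simulate
from sstdbkit.synthetic_data import SimulationConfig


# ---------------------------------------------------------------------------
# Independent oracles (deliberately different implementations from the
# package's own code paths).
# ---------------------------------------------------------------------------

def orf_oracle(seq: str, min_len: int) -> set[tuple[int, str, int, int]]:
    """Enumerate ORFs of all 6 frames via Biopython translation + regex split.

    Valid only for transcripts over {A,C,G,T} (no ambiguity codes).
    """
    out = set()
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        n_codons = (len(s) - off) // 3
        aa = str(Seq(s[off : off + 3 * n_codons]).translate(table=1))
        for m in re.finditer(r"[^*]+", aa):
            if m.end() - m.start() > min_len:
                lo = off + 3 * m.start()
                hi = off + 3 * m.end()
                if frame > 0:
                    start, end = lo, hi
                else:
                    start, end = L - hi, L - lo
                out.add((frame, m.group(), start, end))
    return out


def digest_oracle(seq: str, max_missed: int) -> set[tuple[int, str]]:
    """Brute-force tryptic peptides as (start, sequence) pairs."""
    sites = [i + 1 for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + sites + [len(seq)]
    peps = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(bounds))):
            peps.add((bounds[a], seq[bounds[a] : bounds[b]]))
    return peps


def min_set_cover_size(mapping: dict[str, set[str]]) -> int:
    """Exhaustive minimum number of entry peptide-sets covering all peptides."""
    by_entry: dict[str, set[str]] = {}
    for pep, accs in mapping.items():
        for acc in accs:
            by_entry.setdefault(acc, set()).add(pep)
    universe = set(mapping)
    distinct = list({frozenset(s) for s in by_entry.values()})
    for k in range(1, len(distinct) + 1):
        for combo in itertools.combinations(distinct, k):
            if set().union(*combo) == universe:
                return k
    raise AssertionError("unreachable: the full collection always covers")


def random_peptide_map(rng: np.random.Generator, n_entries: int, n_peptides: int) -> dict[str, set[str]]:
    """Random peptide->entries map where every peptide hits >=1 entry."""
    mapping: dict[str, set[str]] = {}
    for j in range(n_peptides):
        k = int(rng.integers(1, max(2, n_entries // 2 + 1)))
        accs = rng.choice(n_entries, size=k, replace=False)
        mapping[f"PEP{j:02d}"] = {f"E{a:02d}" for a in accs}
    return mapping


# ---------------------------------------------------------------------------
# Shared end-to-end run (session-scoped: the pipeline is deterministic).
# ---------------------------------------------------------------------------

SMALL_SIM = dict(
    n_proteins=30,
    n_noncoding_transcripts=30,
    n_spectra=2000,
    n_contaminants=20,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    return SimulationConfig(**SMALL_SIM)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, small_sim_config):
    """One simulate + run_pipeline round used by several tests."""
    root = tmp_path_factory.mktemp("e2e")
    paths = simulate(small_sim_config, root / "inputs")
    cfg = PipelineConfig(
        transcripts=str(paths["transcripts"]),
        orthologues=str(paths["orthologues"]),
        contaminants=str(paths["contaminants"]),
        psms=str(paths["psms"]),
        blast=str(paths["blast"]),
    )
    outputs = run_pipeline(cfg, root / "out")
    return {"inputs": paths, "outputs": outputs, "config": cfg, "root": root}
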