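"""Ground-truth generators: round trips, determinism, calibration."""

import numpy as np
import pytest

from sstdbkit.sequence_db import six_frame_translate, write_fasta
from sstdbkit.synthetic_data import (
    SimulationConfig,
    generate_orthologue_db,
    generate_proteome,
    generate_psms,
    generate_transcripts,
    write_psm_rows,
)


def cfg(**kw):
    return SimulationConfig(**kw)


class TestGenerateProteome:
    def test_empty_proteome(self):
        assert generate_proteome(cfg(n_proteins=0)) == []

    def test_deterministic_fasta_bytes(self, tmp_path):
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(generate_proteome(cfg(n_proteins=50, rng_seed=1)), a)
        write_fasta(generate_proteome(cfg(n_proteins=50, rng_seed=1)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_mean_length_near_configured(self):
        prots = generate_proteome(cfg(n_proteins=500, protein_length_mean=400, protein_length_sd=50))
        lengths = np.array([len(p) for p in prots])
        # LLN: sample mean within 3 standard errors of 400
        assert abs(lengths.mean() - 400) < 3 * 50 / np.sqrt(500)

    def test_standard_alphabet_only(self):
        prots = generate_proteome(cfg(n_proteins=20))
        assert all(set(p.sequence) <= set("ACDEFGHIKLMNPQRSTVWY") for p in prots)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cfg(p_correct=1.5)
        with pytest.raises(ValueError):
            cfg(n_proteins=-1)


class TestGenerateTranscripts:
    def test_minimal_transcript_length_arithmetic(self):
        # one 60-residue protein with no UTR: CDS + one terminal stop codon
        prot = generate_proteome(cfg(n_proteins=1, protein_length_mean=60, protein_length_sd=0, min_protein_length=60))
        transcripts, truth = generate_transcripts(prot, cfg(utr_length_range=(0, 0)))
        assert len(transcripts[0].sequence) == 3 * 60 + 3

    def test_round_trip_recovers_protein_among_orfs(self):
        config = cfg(n_proteins=15, rng_seed=3)
        proteome = generate_proteome(config)
        transcripts, truth = generate_transcripts(proteome, config)
        by_id = {p.accession: p.sequence for p in proteome}
        for t, record in zip(transcripts, truth):
            if record.protein_id is None:
                continue
            orfs = six_frame_translate(t, min_len=60)
            assert by_id[record.protein_id] in {o.aa_sequence for o in orfs}
            match = [o for o in orfs if o.aa_sequence == by_id[record.protein_id]]
            assert (match[0].frame, match[0].start, match[0].end) == (
                record.frame,
                record.start,
                record.end,
            )

    def test_reverse_strand_recovered_only_in_negative_frame(self):
        config = cfg(n_proteins=40, rng_seed=4)
        proteome = generate_proteome(config)
        transcripts, truth = generate_transcripts(proteome, config)
        by_id = {p.accession: p.sequence for p in proteome}
        reverse_records = [r for r in truth if r.frame is not None and r.frame < 0]
        assert reverse_records, "seeded run must embed some proteins on the reverse strand"
        for record in reverse_records:
            t = next(x for x in transcripts if x.accession == record.transcript_id)
            frames = {
                o.frame
                for o in six_frame_translate(t, min_len=60)
                if o.aa_sequence == by_id[record.protein_id]
            }
            assert frames and all(f < 0 for f in frames)

    def test_nothing_to_generate_rejected(self):
        with pytest.raises(ValueError):
            generate_transcripts([], cfg(n_noncoding_transcripts=0))


class TestGenerateOrthologues:
    def test_zero_divergence_identity(self):
        config = cfg(n_proteins=10, orthologue_fraction=1.0, orthologue_divergence=0.0,
                     unrelated_fraction=0.0)
        proteome = generate_proteome(config)
        orth, mapping = generate_orthologue_db(proteome, config)
        by_id = {p.accession: p.sequence for p in proteome}
        assert len(orth) == 10
        for e in orth:
            assert e.sequence == by_id[mapping[e.accession]]

    def test_full_divergence_identity_matches_closed_form(self):
        # divergence 1 with a 4-letter alphabet: every residue redrawn
        # uniformly, expected identity 1/4
        config = cfg(n_proteins=20, protein_length_mean=500, protein_length_sd=0,
                     min_protein_length=500, orthologue_fraction=1.0,
                     orthologue_divergence=1.0, unrelated_fraction=0.0, rng_seed=9)
        proteome = generate_proteome(config)
        orth, mapping = generate_orthologue_db(proteome, config, alphabet="ACDE")
        by_id = {p.accession: p.sequence for p in proteome}
        matches = total = 0
        for e in orth:
            src = by_id[mapping[e.accession]]
            matches += sum(a == b for a, b in zip(src, e.sequence))
            total += len(src)
        p_hat = matches / total
        # note: source is over 20 letters, substitute over 4 -> identity only
        # where the draw reproduces the original, bounded by 1/4 * fraction of
        # source residues inside the substitution alphabet; use the exact form
        in_alpha = sum(
            sum(c in "ACDE" for c in by_id[p.accession]) for p in proteome
        ) / total
        expected = in_alpha * 0.25
        assert p_hat == pytest.approx(expected, abs=3 * np.sqrt(0.25 * 0.75 / total))

    def test_zero_fraction_gives_only_unrelated(self):
        config = cfg(n_proteins=10, orthologue_fraction=0.0, unrelated_fraction=0.2)
        orth, mapping = generate_orthologue_db(generate_proteome(config), config)
        assert mapping == {}
        assert all(e.accession.startswith("VPDB_U") for e in orth)

    def test_unrelated_share_of_database(self):
        config = cfg(n_proteins=100, orthologue_fraction=0.8, unrelated_fraction=0.2)
        orth, mapping = generate_orthologue_db(generate_proteome(config), config)
        n_unrelated = sum(1 for e in orth if e.accession not in mapping)
        assert n_unrelated / len(orth) == pytest.approx(0.2, abs=0.02)


class TestGeneratePsms:
    POOL_T = [("GAVLKGAVLK", ("S1",)), ("PEWDKPEWDK", ("S2", "V1"))]
    POOL_D = [("KLVAGKLVAG", ("REV_S1",))]

    def test_all_correct_no_decoy_hits(self):
        rows, labels = generate_psms(self.POOL_T, self.POOL_D, cfg(n_spectra=200, p_correct=1.0))
        assert all(labels.values())
        assert all(not r.accessions[0].startswith("REV_") for r in rows)

    def test_labels_cover_every_psm_exactly_once(self):
        rows, labels = generate_psms(self.POOL_T, self.POOL_D, cfg(n_spectra=500))
        assert {r.spectrum_id for r in rows} == set(labels)
        assert len(rows) == 500

    def test_decoys_never_labeled_correct(self):
        rows, labels = generate_psms(self.POOL_T, self.POOL_D, cfg(n_spectra=2000, p_correct=0.5))
        for r in rows:
            if all(a.startswith("REV_") for a in r.accessions):
                assert not labels[r.spectrum_id]

    def test_deterministic_tsv_bytes(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for path in (a, b):
            rows, _ = generate_psms(self.POOL_T, self.POOL_D, cfg(n_spectra=300, rng_seed=5))
            write_psm_rows(rows, path)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            generate_psms([], self.POOL_D, cfg())
        with pytest.raises(ValueError):
            generate_psms(self.POOL_T, [], cfg())

    def test_decoy_fdr_calibrated_against_labels(self):
        # at the score threshold where label-truth FDR is 5%, the decoy
        # estimate agrees within +-2 percentage points
        config = cfg(n_spectra=10_000, p_correct=0.7, rng_seed=11)
        rows, labels = generate_psms(self.POOL_T, self.POOL_D, config)
        data = sorted(
            (
                (r.score, labels[r.spectrum_id], all(a.startswith("REV_") for a in r.accessions))
                for r in rows
            ),
            key=lambda x: -x[0],
        )
        n_target = n_decoy = n_incorrect_target = 0
        best = None
        for score, correct, is_decoy in data:
            if is_decoy:
                n_decoy += 1
            else:
                n_target += 1
                if not correct:
                    n_incorrect_target += 1
            if n_target:
                true_fdr = 100.0 * n_incorrect_target / n_target
                est_fdr = 100.0 * n_decoy / n_target
                if best is None or abs(true_fdr - 5.0) < abs(best[0] - 5.0):
                    best = (true_fdr, est_fdr)
        true_fdr, est_fdr = best
        assert abs(est_fdr - true_fdr) <= 2.0
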