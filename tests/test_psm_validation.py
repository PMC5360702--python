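"""PSM table I/O, mixture-model posteriors, filtering and decoy FDR."""

import numpy as np
import pytest

from sstdbkit.digestion import Peptide
from sstdbkit.psm_validation import (
    ACCEPTED,
    PSM,
    FdrEstimate,
    MixtureFit,
    assign_posteriors,
    filter_psms,
    fit_mixture,
    read_psm_table,
    write_psm_table,
)
from sstdbkit.sequence_db import SearchDatabase, SequenceEntry, concatenate_dbs


def make_db():
    return concatenate_dbs(
        [SequenceEntry("S1", "MGAVLKSTYR" * 8)],
        [SequenceEntry("V1", "MRPEWKDHFC" * 8)],
        [],
    )


def make_psm(sid, seq, score, entries, posterior=None):
    return PSM(
        spectrum_id=sid,
        peptide=Peptide(seq),
        score=score,
        matched_entries=tuple(entries),
        posterior=posterior,
    )


class TestPsmTableIO:
    def test_empty_file_with_header(self, tmp_path):
        db = make_db()
        path = tmp_path / "psms.tsv"
        path.write_text("spectrum_id\tpeptide\tmods\tscore\taccessions\n")
        assert read_psm_table(path, db) == []

    def test_round_trip_is_identity(self, tmp_path):
        db = make_db()
        psms = [
            make_psm("s1", "GAVLK", 3.2, [("S1", "SSTDB", False)]),
            make_psm("s1", "AVGLK", 3.2, [("S1", "SSTDB", False)]),
            make_psm("s2", "PEWK", -0.5, [("V1", "VPDB", False), ("REV_S1", "SSTDB", True)]),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_psm_table(psms, p1)
        back = read_psm_table(p1, db)
        write_psm_table(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [(p.spectrum_id, p.peptide.sequence, p.matched_entries) for p in back] == [
            (p.spectrum_id, p.peptide.sequence, p.matched_entries) for p in psms
        ]

    def test_unknown_accession_named_in_error(self, tmp_path):
        db = make_db()
        path = tmp_path / "psms.tsv"
        path.write_text(
            "spectrum_id\tpeptide\tmods\tscore\taccessions\ns1\tGAVLK\t\t1.0\tNOPE\n"
        )
        with pytest.raises(KeyError, match="NOPE"):
            read_psm_table(path, db)

    def test_malformed_row_reports_line_number(self, tmp_path):
        db = make_db()
        path = tmp_path / "psms.tsv"
        path.write_text(
            "spectrum_id\tpeptide\tmods\tscore\taccessions\n"
            "s1\tGAVLK\t\t1.0\tS1\n"
            "s2\tGAVLK\t1.0\tS1\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_psm_table(path, db)


class TestMixture:
    def _scores(self, n=10_000, pi=0.7, seed=42):
        rng = np.random.default_rng(seed)
        n_c = int(round(pi * n))
        return np.concatenate([rng.normal(4, 1, n_c), rng.normal(0, 1, n - n_c)]), pi

    def test_recovers_mixing_proportion(self):
        scores, pi = self._scores()
        fit = fit_mixture(scores)
        assert not fit.degenerate
        assert fit.pi_correct == pytest.approx(pi, abs=0.03)
        assert fit.mu_incorrect < fit.mu_correct
        assert fit.mu_correct == pytest.approx(4.0, abs=0.1)

    def test_agrees_with_independent_em_implementation(self):
        # scikit-learn's GaussianMixture as an independent cross-check
        from sklearn.mixture import GaussianMixture

        scores, _ = self._scores(seed=1)
        fit = fit_mixture(scores)
        gm = GaussianMixture(n_components=2, random_state=0, tol=1e-8, n_init=3).fit(
            scores.reshape(-1, 1)
        )
        hi = int(np.argmax(gm.means_.ravel()))
        assert fit.mu_correct == pytest.approx(gm.means_.ravel()[hi], abs=0.05)
        assert fit.pi_correct == pytest.approx(gm.weights_[hi], abs=0.02)

    def test_degenerate_scores_take_fallback_path(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_mixture(np.ones(100))
        assert fit.degenerate

    def test_posterior_monotone_for_equal_variances(self):
        fit = MixtureFit(0.0, 4.0, 1.0, 1.0, 0.6, 1, 0.0)
        grid = np.linspace(-5, 10, 500)
        post = fit.posterior(grid)
        assert np.all(np.diff(post) >= -1e-12)
        assert np.all((post >= 0) & (post <= 1))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_mixture(np.arange(10.0))


class TestFilterAndFdr:
    def test_fdr_formula_on_hand_counts(self):
        assert FdrEstimate("psm", 0, 10).fdr == 0.0
        assert FdrEstimate("psm", 1, 50).fdr == 2.0
        assert FdrEstimate("protein_cluster", 13, 1397).fdr == 0.93

    def test_no_targets_is_an_error(self):
        with pytest.raises(ValueError):
            FdrEstimate("psm", 0, 0)

    def test_accept_strictly_above_threshold(self):
        psms = [
            make_psm("s1", "GAVLK", 5.0, [("S1", "SSTDB", False)], posterior=0.96),
            make_psm("s2", "GAVLK", 2.0, [("S1", "SSTDB", False)], posterior=0.95),
        ]
        accepted, fdr, _ = filter_psms(psms, threshold=0.95)
        assert [p.spectrum_id for p in accepted] == ["s1"]
        assert fdr.fdr == 0.0

    def test_filtering_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        psms = [
            make_psm(f"s{i}", "GAVLK", 0.0, [("S1", "SSTDB", False)], posterior=float(p))
            for i, p in enumerate(rng.random(200))
        ]
        sizes = [
            len(filter_psms(psms, threshold=t)[0]) for t in (0.5, 0.7, 0.9, 0.95)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_peptide_level_collapses_il_and_keeps_mods(self):
        psms = [
            make_psm("s1", "IVDK", 1.0, [("S1", "SSTDB", False)], posterior=0.99),
            make_psm("s2", "LVDK", 1.0, [("S1", "SSTDB", False)], posterior=0.99),
            make_psm(
                "s3",
                "LVDK",
                1.0,
                [("S1", "SSTDB", False)],
                posterior=0.99,
            ),
        ]
        psms[2].peptide = Peptide("LVDK", modifications=((0, "Oxidation", 15.99491),))
        _, _, pep_fdr = filter_psms(psms, threshold=0.95)
        # IVDK and LVDK are one peptide; the modified LVDK is a second
        assert pep_fdr.n_target == 2

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            filter_psms([], threshold=1.0)

    def test_decoy_calibration_on_synthetic_scores(self):
        # decoy-estimated FDR tracks label-based truth at the 95% cut
        rng = np.random.default_rng(123)
        psms, truth = [], []
        for i in range(10_000):
            correct = rng.random() < 0.7
            if correct:
                score, entry = rng.normal(4, 1), ("S1", "SSTDB", False)
            else:
                score = rng.normal(0, 1)
                entry = ("S1", "SSTDB", False) if rng.random() < 0.5 else ("REV_S1", "SSTDB", True)
            psms.append(make_psm(f"s{i}", "GAVLK", float(score), [entry]))
            truth.append((correct, entry[2]))
        assign_posteriors(psms)
        accepted, fdr, _ = filter_psms(psms, threshold=0.95)
        ids = {p.spectrum_id for p in accepted}
        true_fdr = (
            100.0
            * sum(1 for i, (c, d) in enumerate(truth) if f"s{i}" in ids and not c and not d)
            / sum(1 for i, (c, d) in enumerate(truth) if f"s{i}" in ids and not d)
        )
        assert abs(fdr.fdr - true_fdr) <= 2.0
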