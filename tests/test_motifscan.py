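"""Catalog loading, PWM log-odds scanning and presence matrices."""

import numpy as np
import pytest

from ferrocre.motifdisc import Motif, iupac_pattern
from ferrocre.motifscan import (
    PWM,
    load_known_catalog,
    presence_matrix,
    pwm_logodds_scan,
    read_meme,
    read_motif_tsv,
    scan_window,
    write_meme,
    write_motif_tsv,
)
from ferrocre.seqio import PromoterWindow, WindowSpec
from ferrocre.synthgen import IUPAC


class TestCatalog:
    def test_contains_idrs(self):
        cat = {m.name: m for m in load_known_catalog()}
        assert cat["IDRS"].consensus == "CCTCCAC"

    def test_contains_idef1_binding(self):
        consensi = {m.consensus for m in load_known_catalog()}
        assert "CATGCATG" in consensi

    def test_ide2_expands_to_caagttt(self):
        cat = {m.name: m for m in load_known_catalog()}
        ide2 = cat["IDE2"].consensus
        assert ide2 == "CAMGYHH"
        assert all(b in IUPAC[c] for b, c in zip("CAAGTTT", ide2))
        assert iupac_pattern(ide2).search("CAAGTTT")

    def test_sources_partition(self):
        sources = {m.source for m in load_known_catalog()}
        assert sources == {"catalog:known-Fe", "catalog:PLACE-like"}

    def test_tsv_roundtrip(self, tmp_path):
        cat = load_known_catalog()
        p = tmp_path / "catalog.tsv"
        write_motif_tsv(cat, p)
        assert read_motif_tsv(p) == cat


def _consensus_pwm(consensus: str, background=None) -> PWM:
    rows = []
    for b in consensus:
        row = [0.0] * 4
        row["ACGT".index(b)] = 1.0
        rows.append(row)
    kwargs = {} if background is None else {"background": background}
    return PWM("test", np.asarray(rows), **kwargs)


class TestPWM:
    def test_deterministic_pwm_max_score_two_bits_per_base(self):
        pwm = _consensus_pwm("ACGT", background=(0.25,) * 4)
        assert pwm.max_score() == pytest.approx(8.0)
        hits = pwm_logodds_scan("ACGT", pwm, threshold_fraction=1.0)
        assert hits == [(0, pytest.approx(8.0))]

    def test_threshold_one_only_exact_sites(self):
        pwm = _consensus_pwm("ACGT", background=(0.25,) * 4)
        hits = pwm_logodds_scan("ACGAACGT", pwm, threshold_fraction=1.0)
        assert [h[0] for h in hits] == [4]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet(np.ones(4), size=4)
        pwm = PWM("rand", probs, background=(0.25,) * 4)
        seq = "".join(rng.choice(list("ACGT"), 30))
        threshold = 0.7
        lo = np.log2(probs / 0.25)
        cutoff = threshold * lo.max(axis=1).sum()
        expected = [
            i
            for i in range(len(seq) - 3)
            if sum(lo[j, "ACGT".index(seq[i + j])] for j in range(4)) >= cutoff
        ]
        got = [h[0] for h in pwm_logodds_scan(seq, pwm, threshold)]
        assert got == expected

    def test_n_blocks_hits(self):
        pwm = _consensus_pwm("ACGT", background=(0.25,) * 4)
        assert pwm_logodds_scan("ACNT", pwm, 0.1) == []

    def test_zero_background_with_nonzero_column_rejected(self):
        with pytest.raises(ValueError, match="background"):
            _consensus_pwm("ACGT", background=(0.5, 0.5, 0.0, 0.0))

    def test_row_sums_validated(self):
        with pytest.raises(ValueError):
            PWM("bad", np.array([[0.5, 0.5, 0.5, 0.0]]))

    def test_meme_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        pwms = [
            PWM("m1", rng.dirichlet(np.ones(4), size=6)),
            PWM("m2", rng.dirichlet(np.ones(4), size=4)),
        ]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == ["m1", "m2"]
        for a, b in zip(pwms, back):
            assert np.allclose(a.probabilities, b.probabilities, atol=1e-6)
            assert np.allclose(a.background, b.background, atol=1e-5)


def _window(gene_id, seq, spec=WindowSpec(-500, 150)):
    return PromoterWindow(gene_id, spec, seq)


class TestPresenceMatrix:
    def test_absent_motif_scores_zero(self):
        windows = {"g1": _window("g1", "A" * 100)}
        fm = presence_matrix(windows, [Motif("IDRS", "CCTCCAC")])
        assert fm.loc["g1", "IDRS"] == 0

    def test_planted_gene_scores_one(self, small_dataset, small_windows):
        fm = presence_matrix(small_windows, [Motif("IDEF1_binding", "CATGCATG")])
        planted = {
            g for g, m, rel in small_dataset.truth_hits
            if m == "CATGCATG" and -500 <= rel <= 150 - 8
        }
        assert (fm.loc[sorted(planted), "IDEF1_binding"] == 1).all()

    def test_window_choice_changes_matrix(self):
        # motif at +50 is seen by -500..+150 but not by the upstream-only window
        seq_up = "A" * 500
        seq_scan = "A" * 550 + "CCTCCAC" + "A" * 93
        up = {"g": _window("g", seq_up, WindowSpec(-500, 0))}
        scan = {"g": _window("g", seq_scan, WindowSpec(-500, 150))}
        motif = [Motif("IDRS", "CCTCCAC")]
        assert presence_matrix(up, motif).loc["g", "IDRS"] == 0
        assert presence_matrix(scan, motif).loc["g", "IDRS"] == 1

    def test_idempotent_and_order_invariant(self, small_windows):
        motifs = [Motif("a", "CATGC"), Motif("b", "AGCTAGCT")]
        ids = list(small_windows)
        fwd = presence_matrix({g: small_windows[g] for g in ids}, motifs)
        rev = presence_matrix({g: small_windows[g] for g in reversed(ids)}, motifs)
        assert fwd.equals(rev)
        assert fwd.isin([0, 1]).all().all()

    def test_duplicate_names_rejected(self, small_windows):
        with pytest.raises(ValueError):
            presence_matrix(small_windows, [Motif("x", "ACGT"), Motif("x", "TTTT")])

    def test_background_presence_matches_analytic_rate(self):
        """Column mean over background-only windows approximates
        1 - (1 - p_site)^(L - w + 1) with p_site from base composition."""
        from ferrocre.motifdisc import random_background

        comp = {"A": 0.26, "C": 0.24, "G": 0.24, "T": 0.26}
        L, w = 650, 8
        consensus = "CATGCATG"
        windows = {
            f"g{i}": _window(f"g{i}", seq)
            for i, seq in enumerate(random_background(650 * 3000, comp, L, seed=11))
        }
        fm = presence_matrix(windows, [Motif("m", consensus)])
        p_site = np.prod([comp[b] for b in consensus])
        expected = 1 - (1 - p_site) ** (L - w + 1)
        assert abs(fm["m"].mean() - expected) < 0.03

    def test_both_strands_flag_adds_reverse_hits(self):
        windows = {"g": _window("g", "TTT" + "GCATGCAT" + "TTT")}
        motif = [Motif("m", "ATGCATGC")]
        assert presence_matrix(windows, motif).loc["g", "m"] == 0
        assert presence_matrix(windows, motif, both_strands=True).loc["g", "m"] == 1


def test_scan_window_offsets(small_windows):
    w = _window("g", "AACATGCATGAA")
    assert scan_window(w, Motif("m", "CATGCATG")) == [2]
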