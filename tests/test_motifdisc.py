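"""Motif counting, enrichment ratio, binomial null and k-mer discovery."""

import math

import numpy as np
import pytest

from ferrocre.motifdisc import (
    Motif,
    binom_pvalue,
    count_occurrences,
    discover_kmers,
    enrichment_ratio,
    iupac_pattern,
    merge_to_iupac,
    random_background,
    score_motif,
)


def sliding_count(seq: str, consensus: str) -> int:
    """Independent exhaustive oracle: test every offset against the IUPAC sets."""
    from ferrocre.synthgen import IUPAC

    w = len(consensus)
    return sum(
        all(seq[i + j] in IUPAC[consensus[j]] for j in range(w))
        for i in range(len(seq) - w + 1)
    )


class TestCounting:
    def test_overlapping_tandem_occurrences(self):
        seq = "GCAGCAGCAGC"
        assert sliding_count(seq, "GCWGCWGC") == 2
        total, genes = count_occurrences([seq], Motif("m", "GCWGCWGC"))
        assert (total, genes) == (2, 1)

    def test_degenerate_w_matches_both_letters(self):
        for seq in ("GCAGCAGC", "GCTGCTGC"):
            assert count_occurrences([seq], Motif("m", "GCWGCWGC")) == (1, 1)

    def test_empty_window_set(self):
        assert count_occurrences([], Motif("m", "ACGT")) == (0, 0)

    def test_motif_wider_than_windows(self):
        assert count_occurrences(["ACG", "TTT"], Motif("m", "ACGTACGT")) == (0, 0)

    def test_n_in_sequence_matches_nothing(self):
        assert count_occurrences(["CANGC"], Motif("m", "CANGC")) == (0, 0)
        assert count_occurrences(["CATGC"], Motif("m", "CANGC")) == (1, 1)

    def test_matches_sliding_oracle_on_random_sequence(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 400))
        for consensus in ("CATGC", "GANTTNC", "CAMGYHH", "AGCTAGCT"):
            total, _ = count_occurrences([seq], Motif("m", consensus))
            assert total == sliding_count(seq, consensus)


class TestEnrichmentRatio:
    def test_worked_example(self):
        assert enrichment_ratio(4, 1000, 10, 10000) == pytest.approx(4.0)

    def test_identity_when_rates_equal(self):
        assert enrichment_ratio(5, 1000, 50, 10000) == pytest.approx(1.0)

    def test_doubling_background_length_doubles_enrichment(self):
        e1 = enrichment_ratio(4, 1000, 10, 10000)
        e2 = enrichment_ratio(4, 1000, 10, 20000)
        assert e2 == pytest.approx(2 * e1)

    def test_zero_background_gives_infinity(self):
        assert math.isinf(enrichment_ratio(3, 100, 0, 1000))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(-1, 100, 5, 100)


def exact_binom_tail(k: int, n: int, p: float) -> float:
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestBinomPvalue:
    def test_zero_hits_whole_mass(self):
        assert binom_pvalue(0, 10, 0.3) == 1.0

    def test_worked_example(self):
        assert binom_pvalue(3, 5, 0.1) == pytest.approx(
            exact_binom_tail(3, 5, 0.1), abs=1e-12
        )
        assert binom_pvalue(3, 5, 0.1) == pytest.approx(0.00856, abs=5e-6)

    def test_degenerate_p_one(self):
        assert binom_pvalue(5, 5, 1.0) == 1.0

    def test_matches_exact_tail_on_grid(self):
        for n in range(1, 51, 7):
            for p in np.arange(0.01, 0.99, 0.07):
                for k in range(0, n + 1, max(1, n // 4)):
                    assert binom_pvalue(k, n, float(p)) == pytest.approx(
                        exact_binom_tail(k, n, float(p)), abs=1e-12
                    )

    def test_monotone_in_hits(self):
        prev = 1.1
        for k in range(0, 21):
            cur = binom_pvalue(k, 20, 0.3)
            assert cur <= prev
            prev = cur


class TestDiscovery:
    def test_top_m_caps_output(self, small_windows):
        reg = dict(list(small_windows.items())[:50])
        res = discover_kmers(reg, small_windows, k=6, top_m=5, correction=None, alpha=1.0)
        assert len(res) <= 5

    def test_ranking_deterministic(self, small_windows):
        reg = dict(list(small_windows.items())[:80])
        a = discover_kmers(reg, small_windows, k=8)
        b = discover_kmers(reg, small_windows, k=8)
        assert [r.motif.consensus for r in a] == [r.motif.consensus for r in b]

    def test_planted_motif_found(self, small_dataset, small_windows):
        storage = {
            g: small_windows[g]
            for g, c in small_dataset.truth_labels.items()
            if c == "storage"
        }
        res = discover_kmers(storage, small_windows, k=8)
        assert "CATGCATG" in [r.motif.consensus for r in res[:5]]

    def test_zero_length_background_rejected(self, small_windows):
        with pytest.raises(ValueError):
            discover_kmers(dict(list(small_windows.items())[:5]), [], k=8)

    def test_enrichment_invariant_to_window_order(self, small_windows):
        ids = list(small_windows)[:60]
        fwd = score_motif("CATGCATG", [small_windows[g] for g in ids], small_windows.values())
        rev = score_motif(
            "CATGCATG", [small_windows[g] for g in reversed(ids)], small_windows.values()
        )
        assert fwd.enrichment == rev.enrichment and fwd.pvalue == rev.pvalue


class TestMergeToIupac:
    windows = ["GCAGCAGCTT", "GCTGCTGCAA", "ACGTACGTAC"]

    def _results(self, kmers):
        return [score_motif(k, self.windows, self.windows * 3) for k in kmers]

    def test_family_merges_to_w(self):
        merged = merge_to_iupac(
            self._results(["GCAGCAGC", "GCTGCTGC"]), self.windows, self.windows * 3,
            max_mismatch=2,
        )
        assert [m.motif.consensus for m in merged] == ["GCWGCWGC"]

    def test_single_motif_unchanged(self):
        merged = merge_to_iupac(self._results(["ACGTACGT"]), self.windows, self.windows * 3)
        assert [m.motif.consensus for m in merged] == ["ACGTACGT"]

    def test_distant_motifs_not_merged(self):
        merged = merge_to_iupac(
            self._results(["AAAAAAAA", "TTTTTTTT"]), self.windows, self.windows * 3,
            max_mismatch=1,
        )
        assert sorted(m.motif.consensus for m in merged) == ["AAAAAAAA", "TTTTTTTT"]

    def test_mixed_widths_rejected(self):
        with pytest.raises(ValueError):
            merge_to_iupac(
                self._results(["AAAA", "TTTTT"]), self.windows, self.windows
            )


class TestRandomBackground:
    def test_base_frequencies_converge(self):
        comp = {b: 0.25 for b in "ACGT"}
        windows = random_background(4_000_000, comp, 650, seed=0)
        seq = "".join(windows)
        for b in "ACGT":
            assert abs(seq.count(b) / len(seq) - 0.25) < 0.002

    def test_deterministic_per_seed(self):
        comp = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
        assert random_background(5000, comp, 100, seed=3) == random_background(
            5000, comp, 100, seed=3
        )
        assert random_background(5000, comp, 100, seed=3) != random_background(
            5000, comp, 100, seed=4
        )

    def test_window_partitioning(self):
        comp = {b: 0.25 for b in "ACGT"}
        windows = random_background(1000, comp, 300, seed=1)
        assert [len(w) for w in windows] == [300, 300, 300, 100]

    def test_random_background_enrichment_at_least_all_genes(
        self, small_dataset, small_windows
    ):
        """Against pure random background a planted motif's enrichment is
        at least its enrichment against all genes (which also carry
        plantings)."""
        storage = [
            small_windows[g]
            for g, c in small_dataset.truth_labels.items()
            if c == "storage"
        ]
        total = sum(len(w.sequence) for w in small_windows.values())
        rand = random_background(
            total, small_dataset.config.base_composition, 650, seed=9
        )
        e_rand = score_motif("CATGCATG", storage, rand).enrichment
        e_genes = score_motif("CATGCATG", storage, small_windows.values()).enrichment
        assert e_rand >= e_genes


def test_iupac_pattern_overlap_lookahead():
    assert len(iupac_pattern("AGCTAGCT").findall("AGCTAGCTAGCT")) == 2
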