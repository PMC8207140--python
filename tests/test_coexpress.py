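"""DEG filtering, geometric-mean merging, TOM and regulon clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ferrocre.coexpress import (
    ClusterParams,
    cluster_regulons,
    geometric_mean_merge,
    select_deg,
    select_no_response,
    topological_overlap,
)
from ferrocre.synthgen import SynthConfig, class_templates_default, generate_dataset


class TestGeometricMeanMerge:
    def test_ratios_2_and_8_merge_to_4(self):
        m = pd.DataFrame({"x10": [1.0], "x20": [3.0]}, index=["g"])
        out = geometric_mean_merge(m, {"fe": ["x10", "x20"]})
        assert out.loc["g", "fe"] == 2.0  # log2(4)

    def test_single_column_identity(self):
        m = pd.DataFrame({"a": [0.3, -1.0]}, index=["g1", "g2"])
        out = geometric_mean_merge(m, {"a": ["a"]})
        assert (out["a"] == m["a"]).all()

    def test_reciprocal_ratios_cancel(self):
        m = pd.DataFrame({"a": [2.0], "b": [-2.0]}, index=["g"])
        assert geometric_mean_merge(m, {"m": ["a", "b"]}).loc["g", "m"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_merge(pd.DataFrame({"a": [1.0]}), {"m": []})


class TestDegSelection:
    matrix = pd.DataFrame(
        {"c1": [0.5, 0.0, 1.4], "c2": [-1.2, 0.0, 0.2]},
        index=["g1", "gzero", "g3"],
    )

    def test_two_fold_keeps_abs_log2_over_1(self):
        assert select_deg(self.matrix, 2.0) == ["g1", "g3"]

    def test_2_82_fold_requires_1_5(self):
        assert select_deg(self.matrix, 2.82) == []
        m = self.matrix.copy()
        m.loc["g1", "c2"] = -1.51
        assert select_deg(m, 2.82) == ["g1"]

    def test_all_zero_gene_never_kept(self):
        for fold in (1.1, 2.0, 100.0):
            assert "gzero" not in select_deg(self.matrix, fold)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            select_deg(self.matrix, 1.0)


class TestNoResponse:
    def test_least_affected_selected(self):
        m = pd.DataFrame({"c": [0.0, 0.5, 0.9, 2.0]}, index=list("abcd"))
        assert select_no_response(m, n=1) == ["a"]
        assert select_no_response(m, n=3) == ["a", "b", "c"]

    def test_ties_break_by_gene_id(self):
        m = pd.DataFrame({"c": [0.5, 0.5, 0.5]}, index=["z", "a", "m"])
        assert select_no_response(m, n=2) == ["a", "m"]

    def test_short_supply_warns_and_returns_all(self):
        m = pd.DataFrame({"c": [0.0, 3.0]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            assert select_no_response(m, n=5) == ["a"]

    def test_default_returns_100_below_twofold(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.normal(0, 0.5, (400, 7)), index=[f"g{i:04d}" for i in range(400)]
        )
        got = select_no_response(m, n=100)
        assert len(got) == 100
        assert (m.loc[got].abs().max(axis=1) < 1).all()


class TestTOM:
    def brute_force(self, a):
        n = a.shape[0]
        k = a.sum(axis=1)
        tom = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                s = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
                tom[i, j] = (s + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
        return tom

    def test_two_gene_hand_value(self):
        a = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert topological_overlap(a)[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_perfect_overlap_is_one(self):
        a = 1.0 - np.eye(3)
        assert np.allclose(topological_overlap(a), 1.0)

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.random((6, 6))
            a = (x + x.T) / 2
            np.fill_diagonal(a, 0.0)
            assert np.abs(topological_overlap(a) - self.brute_force(a)).max() < 1e-12

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            topological_overlap(np.array([[0.0, 0.2], [0.4, 0.0]]))

    def test_tom_equals_adjacency_for_two_nodes(self):
        rng = np.random.default_rng(1)
        v = rng.random()
        a = np.array([[0.0, v], [v, 0.0]])
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(v, abs=1e-12)


class TestClusterRegulons:
    def _block_matrix(self):
        rng = np.random.default_rng(3)
        base1, base2 = rng.normal(size=7), rng.normal(size=7)
        rows = [base1 * s for s in (1.0, 1.1, 0.9, 1.2)] + [
            base2 * s for s in (1.0, 0.8, 1.3, 1.1)
        ]
        return pd.DataFrame(
            rows,
            index=[f"g{i}" for i in range(8)],
            columns=list(class_templates_default().columns),
        )

    def test_perfect_blocks_recovered(self):
        m = self._block_matrix()
        params = ClusterParams(k_modules=2, min_module_size=2)
        asg = cluster_regulons(m, list(m.index), params)
        mods = asg.module_ids
        assert len(set(mods.iloc[:4])) == 1
        assert len(set(mods.iloc[4:])) == 1
        assert mods.iloc[0] != mods.iloc[-1]

    def test_storage_pattern_gets_storage_label(self):
        t = class_templates_default()
        rng = np.random.default_rng(0)
        rows, ids = [], []
        for cls in ("storage", "uptake", "chelator", "wrky"):
            for r in range(12):
                rows.append(t.loc[cls].to_numpy() + rng.normal(0, 0.2, 7))
                ids.append(f"{cls}{r}")
        m = pd.DataFrame(rows, index=ids, columns=t.columns)
        asg = cluster_regulons(m, ids, ClusterParams(min_module_size=5))
        storage_labels = asg.labels[[g for g in ids if g.startswith("storage")]]
        assert (storage_labels == "storage").all()

    def test_label_assignment_invariant_to_input_order(self):
        m = self._block_matrix()
        params = ClusterParams(k_modules=2, min_module_size=2)
        fwd = cluster_regulons(m, list(m.index), params)
        rev = cluster_regulons(m.iloc[::-1], list(m.index)[::-1], params)
        assert fwd.labels.sort_index().equals(rev.labels.sort_index())

    def test_constant_gene_excluded_with_warning(self):
        m = self._block_matrix()
        m.loc["flat"] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            asg = cluster_regulons(
                m, list(m.index), ClusterParams(k_modules=2, min_module_size=2)
            )
        assert "flat" not in asg.labels.index

    def test_no_response_appended_and_disjoint(self):
        m = self._block_matrix()
        params = ClusterParams(k_modules=2, min_module_size=2)
        asg = cluster_regulons(m, list(m.index[:6]), params, no_response_genes=["x1", "x2"])
        assert (asg.labels[["x1", "x2"]] == "none").all()
        with pytest.raises(ValueError):
            cluster_regulons(m, list(m.index), params, no_response_genes=["g0"])

    def test_synthetic_default_recovers_planted_regulons(self):
        """ARI vs the planted classes at default noise, one seed (the
        10-seed version runs in the acceptance suite)."""
        ds = generate_dataset(SynthConfig(seed=0))
        deg = select_deg(ds.expression, 2.0)
        asg = cluster_regulons(ds.expression, deg)
        resp = [g for g in asg.labels.index if ds.truth_labels[g] != "none"]
        ari = adjusted_rand_score(
            [ds.truth_labels[g] for g in resp], asg.labels.loc[resp]
        )
        assert ari >= 0.9

    def test_beta_sharpens_zero_noise_clusters(self):
        """On a zero-noise draw the ARI is non-decreasing in beta."""
        ds = generate_dataset(SynthConfig(n_genes=200, noise_sd=0.0, seed=4))
        deg = select_deg(ds.expression, 2.0)
        truth = [ds.truth_labels[g] for g in sorted(set(deg))]
        aris = []
        for beta in (1.0, 3.0, 6.0, 9.0):
            asg = cluster_regulons(
                ds.expression, deg, ClusterParams(beta=beta)
            )
            aris.append(adjusted_rand_score(truth, asg.labels.sort_index()))
        assert all(b >= a - 1e-12 for a, b in zip(aris, aris[1:]))
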