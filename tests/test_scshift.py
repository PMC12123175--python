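"""Single-cell stage: QC, normalization, clustering, downsampling, DE,
target-set enrichment, and fold-change shift tests."""

import json

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from subpheno import scshift


def toy_adata(counts, sample="s0", condition="test", **obs_kw):
    n = counts.shape[0]
    obs = pd.DataFrame({
        "sample_id": [sample] * n,
        "condition": [condition] * n,
        "percent_mito": obs_kw.get("percent_mito", np.full(n, 1.0)),
        "percent_ribo": obs_kw.get("percent_ribo", np.full(n, 1.0)),
    }, index=[f"c{i}" for i in range(n)])
    a = ad.AnnData(X=sparse.csr_matrix(np.asarray(counts, dtype=float)), obs=obs)
    return scshift.ensure_qc_fields(a)


class TestQcFilter:
    def _base(self, n=40, g=300, seed=0):
        rng = np.random.default_rng(seed)
        return rng.poisson(2.0, size=(n, g))

    def test_high_mito_removed(self):
        counts = self._base()
        mito = np.full(40, 1.0)
        mito[3] = 6.0
        a = scshift.qc_filter(toy_adata(counts, percent_mito=mito))
        assert "c3" not in a.obs_names
        assert a.uns["qc_report"]["percent_mito"] == 1

    def test_exactly_200_features_retained(self):
        counts = np.zeros((12, 400))
        counts[:, :250] = 1  # plenty of features
        counts[5, :] = 0
        counts[5, :200] = 1  # exactly 200: "below 200" is strict
        counts[6, :] = 0
        counts[6, :199] = 1  # 199: removed
        a = scshift.qc_filter(toy_adata(counts), nfeat_sd=100)
        assert "c5" in a.obs_names and "c6" not in a.obs_names

    def test_generator_truth(self, sc_workspace, sc_adata):
        a = scshift.qc_filter(sc_adata.copy())
        truth = pd.read_csv(sc_workspace["qc_truth"], sep="\t")
        expected = set(truth[truth["removed"]]["cell_id"])
        assert set(a.uns["qc_report"]["removed_cells"]) == expected
        planted = json.loads(sc_workspace["truth"].read_text())["planted_qc_violators"]
        planted_cells = {c for cells in planted.values() for c in cells}
        assert planted_cells <= expected


class TestNormalize:
    def test_depth_invariance(self):
        base = np.array([[1, 2, 0, 4], [2, 4, 0, 8], [5, 1, 1, 1]], dtype=float)
        a = scshift.normalize(toy_adata(base))
        x = a.layers["lognorm"].toarray() if sparse.issparse(a.layers["lognorm"]) \
            else a.layers["lognorm"]
        np.testing.assert_allclose(x[0], x[1], rtol=1e-12)

    def test_constant_gene_never_variable(self):
        # equal depths, genes 2-4 constant: zero normalized variance
        counts = np.ones((10, 5))
        counts[:, 0] = np.arange(1, 11)
        counts[:, 1] = 11 - np.arange(1, 11)
        a = scshift.normalize(toy_adata(counts), n_variable=5)
        hv = a.var["highly_variable"].to_numpy()
        assert hv[0] and hv[1]
        assert not hv[2:].any()

    def test_variable_ranking_matches_dense_oracle(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(3.0, size=(50, 100)).astype(float)
        a = scshift.normalize(toy_adata(counts), n_variable=10)
        x = a.layers["lognorm"]
        x = x.toarray() if sparse.issparse(x) else np.asarray(x)
        oracle = np.argsort(-x.var(axis=0), kind="stable")[:10]
        assert set(np.flatnonzero(a.var["highly_variable"])) == set(oracle)

    def test_zero_depth_cell_rejected(self):
        counts = np.ones((4, 5))
        counts[2] = 0
        with pytest.raises(ValueError, match="zero-depth"):
            scshift.normalize(toy_adata(counts))


class TestClustering:
    def _blobs(self, seed=0, n=120, g=60):
        rng = np.random.default_rng(seed)
        half = n // 2
        mu = np.full(g, 2.0)
        counts = rng.poisson(mu, size=(n, g)).astype(float)
        counts[half:, : g // 3] += rng.poisson(15.0, size=(half, g // 3))
        labels = np.array([0] * half + [1] * (n - half))
        return counts, labels

    def test_single_cluster(self):
        counts, _ = self._blobs()
        a = scshift.normalize(toy_adata(counts))
        a = scshift.cluster_cells(a, k=1)
        assert a.obs["cluster"].nunique() == 1

    def test_two_blobs_recovered(self):
        counts, labels = self._blobs()
        a = scshift.normalize(toy_adata(counts))
        a = scshift.cluster_cells(a, n_pcs=10, k=2)
        got = a.obs["cluster"].to_numpy()
        agreement = max(
            np.mean((got == got[0]) == (labels == labels[0])),
            np.mean((got == got[0]) == (labels != labels[0])),
        )
        assert agreement >= 0.99

    def test_order_invariance_up_to_relabeling(self):
        counts, _ = self._blobs(seed=3)
        a1 = scshift.cluster_cells(scshift.normalize(toy_adata(counts)), n_pcs=5, k=3)
        perm = np.random.default_rng(0).permutation(counts.shape[0])
        a2 = scshift.cluster_cells(
            scshift.normalize(toy_adata(counts[perm])), n_pcs=5, k=3)
        l1 = a1.obs["cluster"].to_numpy()[perm]
        l2 = a2.obs["cluster"].to_numpy()
        mapping = {}
        for x, y in zip(l1, l2):
            assert mapping.setdefault(x, y) == y

    def test_k_exceeding_cells_raises(self):
        counts, _ = self._blobs()
        a = scshift.normalize(toy_adata(counts))
        with pytest.raises(ValueError, match="exceeds"):
            scshift.cluster_cells(a, k=1000)


def _two_condition_adata(n_test=60, n_ctl=40, seed=0, clusters=3):
    rng = np.random.default_rng(seed)
    n = n_test + n_ctl
    counts = rng.poisson(2.0, size=(n, 50)).astype(float)
    a = toy_adata(counts)
    a.obs["condition"] = ["t"] * n_test + ["c"] * n_ctl
    a.obs["cluster"] = pd.Categorical(
        (rng.integers(0, clusters, n)).astype(str))
    return a


class TestDownsample:
    def test_equal_counts_identity(self):
        a = _two_condition_adata(40, 40)
        out = scshift.downsample_to_match(a, "t", "c", seed=1)
        assert out.n_obs == 80

    def test_total_matches_control_and_min_rule(self):
        a = _two_condition_adata(100, 40)
        out = scshift.downsample_to_match(a, "t", "c", seed=1)
        n_t = int((out.obs["condition"] == "t").sum())
        assert n_t == 40
        for cl, grp in out.obs[out.obs["condition"] == "t"].groupby(
                "cluster", observed=True):
            avail = ((a.obs["condition"] == "t") & (a.obs["cluster"] == cl)).sum()
            assert len(grp) <= avail

    def test_preserves_test_cluster_proportions(self):
        a = _two_condition_adata(400, 100, seed=5, clusters=4)
        out = scshift.downsample_to_match(a, "t", "c", seed=2)
        orig = a.obs[a.obs["condition"] == "t"]["cluster"].value_counts(normalize=True)
        kept = out.obs[out.obs["condition"] == "t"]["cluster"].value_counts(normalize=True)
        assert (orig - kept).abs().max() < 0.05

    def test_seed_determinism(self):
        a = _two_condition_adata(100, 40)
        o1 = scshift.downsample_to_match(a, "t", "c", seed=9)
        o2 = scshift.downsample_to_match(a, "t", "c", seed=9)
        assert list(o1.obs_names) == list(o2.obs_names)


class TestDeWilcoxon:
    def test_identical_gene_not_reported(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(80, 20)).astype(float)
        counts[:, 0] = 5.0  # identical in both groups
        a = toy_adata(counts)
        a.obs["condition"] = ["t"] * 40 + ["c"] * 40
        a = scshift.normalize(a)
        de = scshift.de_wilcoxon(a, "t", "c")
        assert "0" not in set(de["gene"])

    def test_low_detection_gene_not_tested(self):
        counts = np.zeros((400, 3))
        counts[:, 0] = 5.0
        counts[0, 1] = 50.0  # detected in 0.5% of either group
        counts[200, 1] = 1.0
        counts[:, 2] = np.random.default_rng(0).poisson(2.0, 400)
        a = toy_adata(counts)
        a.obs["condition"] = ["t"] * 200 + ["c"] * 200
        a = scshift.normalize(a)
        de = scshift.de_wilcoxon(a, "t", "c", min_pct=0.01)
        assert "1" not in set(de["gene"])

    def test_planted_twofold_gene_recovered(self):
        rng = np.random.default_rng(42)
        errs = []
        for rep in range(50):
            counts = rng.poisson(2.0, size=(600, 40)).astype(float)
            counts[:300, 7] = rng.poisson(4.0, 300)  # 2x in test cells
            counts[300:, 7] = rng.poisson(2.0, 300)
            a = toy_adata(counts)
            a.obs["condition"] = ["t"] * 300 + ["c"] * 300
            a = scshift.normalize(a)
            de = scshift.de_wilcoxon(a, "t", "c").set_index("gene")
            assert "7" in de.index
            assert de.loc["7", "direction"] == "up"
            errs.append(de.loc["7", "log2fc"] - 1.0)
        assert np.median(np.abs(errs)) < 0.15

    def test_empty_group_raises(self):
        a = toy_adata(np.ones((5, 5)))
        a.obs["condition"] = "t"
        a = scshift.normalize(a)
        with pytest.raises(ValueError, match="cells"):
            scshift.de_wilcoxon(a, "t", "missing")


class TestTargetSetEnrichment:
    def _de(self, genes, sig_genes):
        return pd.DataFrame({
            "gene": genes,
            "p_adj": [0.01 if g in sig_genes else 0.5 for g in genes],
        })

    def test_all_degs_are_targets_matches_oracle(self):
        from test_network import oracle_hypergeom_upper

        background = [f"g{i}" for i in range(100)]
        targets = background[:5]
        degs = background[:3]
        out = scshift.target_set_enrichment(
            self._de(background, set(degs)), targets, background)
        # upper-tail hypergeometric equals the two-sided Fisher tail here in
        # the direction of enrichment; compare the observed/expected parts
        assert out["observed_frac"] == pytest.approx(1.0)
        assert out["expected_frac"] == pytest.approx(0.05)
        assert out["p"] <= oracle_hypergeom_upper(3, 100, 5, 3) + 1e-10

    def test_empty_target_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            scshift.target_set_enrichment(self._de(["a"], set()), [], ["a"])

    def test_empty_deg_set_warns(self):
        with pytest.warns(UserWarning, match="empty DEG"):
            out = scshift.target_set_enrichment(
                self._de(["a", "b"], set()), ["a"], ["a", "b"])
        assert out["p"] == 1.0

    def test_null_type_one_error(self):
        """Targets drawn like the background give a calibrated test."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_sims = 100
        for _ in range(n_sims):
            background = [f"g{i}" for i in range(400)]
            sig = set(rng.choice(background, 40, replace=False))
            targets = rng.choice(background, 50, replace=False)
            out = scshift.target_set_enrichment(
                self._de(background, sig), targets, background)
            rejections += out["p"] <= 0.05
        assert rejections / n_sims <= 0.07


class TestOrthologMap:
    MAP = pd.DataFrame({
        "human_symbol": ["YTHDF2", "GMEB1", "CHD8", "CHD8"],
        "zebrafish_symbol": ["ythdf2", "gmeb1", "chd8a", "chd8b"],
    })

    def test_unmapped_reported(self):
        mapped, unmapped = scshift.ortholog_map(["YTHDF2", "NOVEL1"], self.MAP)
        assert mapped == ["ythdf2"] and unmapped == ["NOVEL1"]

    def test_one_to_many_kept(self):
        mapped, _ = scshift.ortholog_map(["CHD8"], self.MAP)
        assert mapped == ["chd8a", "chd8b"]

    def test_count_conservation(self):
        genes = ["YTHDF2", "GMEB1", "CHD8", "X1", "X2"]
        mapped, unmapped = scshift.ortholog_map(genes, self.MAP)
        assert len(mapped) + len(unmapped) >= len(genes)


class TestShiftTest:
    def _table(self, kd, oe, n_targets):
        n = len(kd)
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "avg_log2fc_kd": kd,
            "avg_log2fc_oe": oe,
            "in_target_set": [i < n_targets for i in range(n)],
        })

    def test_identical_vectors(self):
        v = np.linspace(-1, 1, 10)
        out = scshift.geneset_shift_test(self._table(v, v, 10))
        assert out["paired_t"] == pytest.approx(0.0)
        assert out["paired_p"] == pytest.approx(1.0)

    def test_matches_hand_computation_on_toy(self):
        kd = np.array([0.10, -0.05, 0.20, 0.00, 0.15])
        oe = np.array([-0.15, -0.20, -0.05, -0.30, -0.10])
        d = oe - kd
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        out = scshift.geneset_shift_test(self._table(kd, oe, 5))
        assert out["paired_t"] == pytest.approx(t_hand, abs=1e-12)

    def test_too_few_targets_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            scshift.geneset_shift_test(self._table([0.1, 0.2], [0.0, 0.1], 2))

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(21)
        detected = 0
        for _ in range(20):
            kd = rng.normal(0, 0.1, 100)
            oe = kd - 0.2 + rng.normal(0, 0.1, 100)
            out = scshift.geneset_shift_test(self._table(kd, oe, 100))
            detected += out["paired_p"] < 1e-6
        assert detected >= 19


class TestEndToEndRecovery:
    def test_planted_downshift_detected(self, sc_workspace, sc_adata):
        """Full stage on the session fixture: negative target fold change
        and significant target-set enrichment."""
        truth = json.loads(sc_workspace["truth"].read_text())
        a = scshift.qc_filter(sc_adata.copy())
        a = scshift.normalize(a)
        a = scshift.cluster_cells(a, n_pcs=20, k=truth["n_clusters"])
        a = scshift.downsample_to_match(a, "overexpression", "oe_control", seed=3)
        de = scshift.de_wilcoxon(a, "overexpression", "oe_control")
        expressed = scshift.average_log2fc(a, "overexpression", "oe_control")
        targets = truth["target_genes"]
        enr = scshift.target_set_enrichment(de, targets, expressed["gene"])
        tgt_fc = expressed[expressed["gene"].isin(targets)]["avg_log2fc"]
        assert tgt_fc.median() < 0
        assert enr["p"] < 0.01
        assert enr["observed_frac"] > enr["expected_frac"]
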