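"""Single-cell pipeline: QC, normalization, regression, PCs, clustering,
cell-cycle scoring."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from invasig import sc, simulate


def make_adata(counts, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    return ad.AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])]),
        var=pd.DataFrame({"is_mito": [g.startswith("MT-") for g in genes]}, index=genes),
    )


def brute_qc(counts, mito_mask, cfg):
    """Literal recount of the QC rules, cell by cell."""
    kept = []
    for i, row in enumerate(counts):
        total = row.sum()
        if total <= cfg.min_barcode_counts:
            continue
        if (row > 0).sum() < cfg.min_genes:
            continue
        if row[mito_mask].sum() / total > cfg.max_mito_fraction:
            continue
        kept.append(i)
    return kept


class TestQC:
    def test_boundary_semantics(self):
        cfg = sc.QCConfig(min_barcode_counts=500, min_genes=3, max_mito_fraction=0.15)
        genes = ["MT-1", "a", "b", "c"]
        rows = [
            [75, 142, 142, 142],   # 501 counts, 4 genes, 15.0% mito -> kept
            [0, 200, 200, 100],    # 500 counts -> removed at barcode stage
            [90, 300, 111, 0],     # 501 counts but 17.9% mito -> removed
            [0, 501, 0, 0],        # 1 gene detected -> removed
        ]
        adata = make_adata(np.array(rows), genes)
        kept = sc.qc_filter(adata, cfg)
        assert list(kept.obs_names) == ["c0"]
        assert kept.obs.loc["c0", "mito_fraction"] == pytest.approx(75 / 501)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        cfg = sc.QCConfig(min_barcode_counts=50, min_genes=10, max_mito_fraction=0.2)
        for _ in range(25):
            genes = ["MT-1", "MT-2"] + [f"g{i}" for i in range(28)]
            counts = rng.poisson(rng.uniform(0.5, 6), size=(20, 30))
            adata = make_adata(counts, genes)
            mito = np.array([g.startswith("MT-") for g in genes])
            want = [f"c{i}" for i in brute_qc(counts, mito, cfg)]
            if not want:
                with pytest.raises(ValueError):
                    sc.qc_filter(adata, cfg)
            else:
                assert list(sc.qc_filter(adata, cfg).obs_names) == want

    def test_planted_low_quality_barcodes_removed_exactly(self):
        cfg = simulate.default_sc_config(7, low_quality_fraction=0.1)
        adata, truth = simulate.gen_sc(cfg)
        kept = sc.qc_filter(adata)
        assert set(kept.obs_names) == set(truth.index[~truth["low_quality"]])

    def test_no_survivors_raises_with_attrition(self):
        adata = make_adata(np.ones((3, 4), int))
        with pytest.raises(ValueError, match="barcodes"):
            sc.qc_filter(adata, sc.QCConfig(min_barcode_counts=500, min_genes=2))


class TestNormalize:
    def test_formula_and_zero(self):
        adata = make_adata([[0, 2, 8], [5, 0, 5]])
        norm = sc.normalize_log(adata)
        assert norm.X[0, 0] == 0.0
        assert norm.X[0, 1] == pytest.approx(np.log(1 + 2 / 10 * 1e4))

    def test_conservation_identity(self):
        rng = np.random.default_rng(1)
        adata = make_adata(rng.poisson(3, size=(30, 50)) + 1)
        norm = sc.normalize_log(adata)
        back = (np.exp(norm.X) - 1).sum(axis=1)
        np.testing.assert_allclose(back, 1e4, rtol=1e-6)

    def test_monotone_in_raw_count(self):
        adata = make_adata([[0, 1, 2, 5, 20]])
        with pytest.raises(ValueError):
            sc.normalize_log(make_adata([[0, 0]]))
        norm = sc.normalize_log(adata)
        assert np.all(np.diff(norm.X[0]) > 0)


class TestRegressOut:
    def test_perfectly_linear_gene_vanishes(self):
        cov = np.linspace(0, 1, 40)
        x = np.outer(cov, [2.0, -1.5]) + 3.0
        adata = make_adata(np.zeros((40, 2), int))
        adata.X = x
        out = sc.regress_out(adata, cov)
        assert np.abs(out.X).max() < 1e-8

    def test_orthogonal_covariate_only_centers(self):
        rng = np.random.default_rng(2)
        cov = np.tile([1.0, -1.0], 20)
        g = np.repeat(rng.normal(size=20), 2)  # symmetric in cov -> orthogonal
        adata = make_adata(np.zeros((40, 1), int))
        adata.X = g[:, None]
        out = sc.regress_out(adata, cov)
        np.testing.assert_allclose(out.X[:, 0], g - g.mean(), atol=1e-10)

    def test_residuals_uncorrelated_with_covariate(self):
        rng = np.random.default_rng(3)
        adata = make_adata(np.zeros((60, 5), int))
        adata.X = rng.normal(size=(60, 5))
        cov = rng.normal(size=60)
        out = sc.regress_out(adata, cov)
        for j in range(5):
            assert abs(np.corrcoef(out.X[:, j], cov)[0, 1]) < 1e-10

    def test_constant_covariate_is_identity_with_warning(self):
        adata = make_adata(np.arange(8).reshape(4, 2))
        adata.X = adata.X.astype(float)
        with pytest.warns(UserWarning):
            out = sc.regress_out(adata, np.ones(4))
        np.testing.assert_array_equal(out.X, adata.X)


class TestSignificantPCs:
    def _noise(self, seed, n=80, g=200):
        rng = np.random.default_rng(seed)
        adata = make_adata(np.zeros((n, g), int))
        adata.X = rng.normal(size=(n, g))
        return adata

    def test_isotropic_noise_selects_fallback_one(self):
        import warnings as w

        hits = 0
        for seed in range(10):
            with w.catch_warnings():
                w.simplefilter("ignore")
                sel = sc.significant_pcs(self._noise(seed), n_perm=30,
                                         perm_gene_fraction=0.1, seed=seed)
            hits += sel.n_components == 1 and sel.pvalues[0] >= sel.alpha
        assert hits >= 9

    def test_three_planted_factors_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, g = 80, 200
            x = rng.normal(size=(n, g))
            for j in range(3):  # three orthogonal block factors of large variance
                x[:, j * 30:(j + 1) * 30] += np.outer(rng.normal(size=n) * 4, np.ones(30))
            adata = make_adata(np.zeros((n, g), int))
            adata.X = x
            sel = sc.significant_pcs(adata, n_perm=30, perm_gene_fraction=0.1, seed=seed)
            hits += sel.n_components == 3
        assert hits >= 9

    def test_fixed_seed_is_deterministic(self):
        adata = self._noise(0)
        with pytest.warns(UserWarning):
            a = sc.significant_pcs(adata, n_perm=25, perm_gene_fraction=0.1, seed=5)
        with pytest.warns(UserWarning):
            b = sc.significant_pcs(adata, n_perm=25, perm_gene_fraction=0.1, seed=5)
        assert a.n_components == b.n_components
        np.testing.assert_array_equal(a.pvalues, b.pvalues)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            sc.significant_pcs(self._noise(1), n_perm=5)


class TestClustering:
    def _blob_data(self, seed=0, n_per=40, k=3):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=12, size=(k, 30))
        x = np.vstack([c + rng.normal(size=(n_per, 30)) for c in centers])
        adata = make_adata(np.zeros(x.shape, int))
        adata.X = x
        truth = np.repeat(np.arange(k), n_per)
        return adata, truth

    def test_well_separated_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        adata, truth = self._blob_data()
        labels = sc.cluster_cells(adata, 3, k_neighbors=30, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_same_seed_identical_labels(self):
        adata, _ = self._blob_data(3)
        a = sc.cluster_cells(adata, 3, k_neighbors=15, seed=9)
        b = sc.cluster_cells(adata, 3, k_neighbors=15, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_labels_in_decreasing_size_order(self):
        adata, _ = self._blob_data(4)
        labels = sc.cluster_cells(adata, 3, k_neighbors=15, seed=1)
        sizes = pd.Series(labels).value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_vanishing_resolution_single_cluster(self):
        # connected graph (single weakly structured cloud): the limit merges all
        rng = np.random.default_rng(5)
        adata = make_adata(np.zeros((90, 30), int))
        adata.X = rng.normal(size=(90, 30))
        adata.X[45:, 0] += 1.0
        labels = sc.cluster_cells(adata, 3, k_neighbors=15, resolution=1e-4, seed=0)
        assert len(set(labels)) == 1


class TestCellCycle:
    def test_decision_rule_and_planted_recovery(self):
        cfg = simulate.default_sc_config(13)
        adata, truth = simulate.gen_sc(cfg)
        norm = sc.regress_out(sc.normalize_log(sc.qc_filter(adata)), "mito_fraction")
        res = sc.cell_cycle_scores(norm, adata.uns["s_genes"], adata.uns["g2m_genes"], seed=13)
        # decision rule: argmax of positive scores, else G1
        s, g2m, phase = res["s_score"], res["g2m_score"], res["phase"]
        assert ((phase == "G1") == (np.maximum(s, g2m) <= 0)).all()
        assert (phase[(s > g2m) & (s > 0)] == "S").all()
        acc = (phase.to_numpy() == truth.loc[res.index, "phase"].to_numpy()).mean()
        assert acc >= 0.9

    def test_missing_phase_genes_error(self):
        adata = make_adata(np.ones((5, 6), int))
        norm = sc.normalize_log(adata)
        with pytest.raises(ValueError):
            sc.cell_cycle_scores(norm, ["absent1"], ["g0"], seed=0)
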