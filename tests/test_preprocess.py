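"""QC boundaries, normalization arithmetic, HVG ranking, PCA determinism,
graph clustering and the Wilcoxon marker machinery."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import crossvasc as cv
from crossvasc.preprocess import bh_adjust, exact_rank_sum_p, log_fold_change

from conftest import make_dataset


def dataset_with_detected_counts(detected):
    """One cell per entry, expressing exactly `detected[i]` genes."""
    n_genes = max(detected) + 1
    rows, cols = [], []
    for i, d in enumerate(detected):
        rows.extend([i] * d)
        cols.extend(range(d))
    counts = sp.csr_matrix(
        (np.ones(len(rows), dtype=int), (rows, cols)), shape=(len(detected), n_genes)
    )
    return cv.ExpressionDataset(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(len(detected))],
        gene_ids=[f"g{j}" for j in range(n_genes)],
        species="Pt",
    )


class TestQC:
    def test_detected_gene_boundaries(self):
        ds = dataset_with_detected_counts([999, 1000, 3000, 7000, 7001])
        kept, report = cv.qc_filter(ds)
        assert kept.cell_ids == ["c1", "c2", "c3"]
        reasons = dict(zip(report["cell_id"], report["reason"]))
        assert reasons == {"c0": "too_few_genes", "c4": "too_many_genes"}

    def test_idempotent(self):
        ds = dataset_with_detected_counts([999, 1500, 2000])
        once, _ = cv.qc_filter(ds)
        twice, report = cv.qc_filter(once)
        assert twice.cell_ids == once.cell_ids and len(report) == 0

    def test_all_cells_removed_raises(self):
        ds = dataset_with_detected_counts([5, 10])
        with pytest.raises(cv.ContractError, match="every cell"):
            cv.qc_filter(ds)


class TestNormalize:
    def test_hand_computed_values(self):
        ds = make_dataset([[1, 3]])
        out = cv.normalize_lognorm(ds, scale=4)
        np.testing.assert_allclose(
            out.normalized.toarray()[0], [np.log(2.0), np.log(4.0)], rtol=1e-12
        )

    def test_all_zero_gene_stays_zero(self):
        ds = make_dataset([[1, 0], [2, 0]])
        out = cv.normalize_lognorm(ds)
        assert out.normalized.toarray()[:, 1].sum() == 0

    def test_scale_invariance_per_cell(self):
        ds1 = make_dataset([[1, 3, 6]])
        ds2 = make_dataset([[2, 6, 12]])
        n1 = cv.normalize_lognorm(ds1).normalized.toarray()
        n2 = cv.normalize_lognorm(ds2).normalized.toarray()
        np.testing.assert_allclose(n1, n2, rtol=1e-12)

    def test_zero_total_cell_named_in_error(self):
        ds = make_dataset([[1, 1], [0, 0]])
        with pytest.raises(cv.ContractError, match="c1"):
            cv.normalize_lognorm(ds)


class TestHVG:
    def test_bimodal_beats_uniform_and_constant_ranks_last(self):
        rng = np.random.default_rng(0)
        n = 60
        bimodal = np.repeat([0.0, 2.0], n // 2)
        uniform = np.full(n, 1.0) + rng.normal(0, 0.05, n)
        constant = np.full(n, 1.0)
        norm = np.column_stack([bimodal, uniform, constant])
        ds = make_dataset(np.zeros_like(norm, dtype=int), normalized=norm)
        ranked = cv.select_hvg(ds, n_top=3)
        assert ranked[0] == "g0"
        assert ranked[-1] == "g2"

    def test_n_top_equal_to_n_genes_is_identity(self):
        rng = np.random.default_rng(1)
        norm = rng.random((30, 8))
        ds = make_dataset(np.zeros_like(norm, dtype=int), normalized=norm)
        assert sorted(cv.select_hvg(ds, n_top=8)) == sorted(ds.gene_ids)

    def test_clamps_with_warning(self):
        ds = make_dataset(np.zeros((5, 3), dtype=int), normalized=np.random.default_rng(2).random((5, 3)))
        with pytest.warns(UserWarning, match="clamp"):
            out = cv.select_hvg(ds, n_top=10)
        assert len(out) == 3


class TestPCA:
    def test_collinear_data_has_all_variance_on_pc1(self):
        rng = np.random.default_rng(3)
        t = rng.random(50)
        norm = np.column_stack([t, 2 * t])
        ds = make_dataset(np.zeros_like(norm, dtype=int), normalized=norm)
        emb = cv.embed_pca(ds, n_pcs=2)
        variances = emb.var(axis=0)
        assert variances[0] / variances.sum() > 0.999999

    def test_reconstruction_error_monotone_in_components(self):
        rng = np.random.default_rng(4)
        x = rng.random((40, 10))
        x = (x - x.mean(0)) / x.std(0)
        errors = []
        for k in range(1, 11):
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            recon = u[:, :k] @ np.diag(s[:k]) @ vt[:k]
            errors.append(np.linalg.norm(x - recon))
        assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(errors, errors[1:]))

    def test_embedding_reproducible(self):
        rng = np.random.default_rng(5)
        norm = rng.random((30, 12))
        ds = make_dataset(np.zeros_like(norm, dtype=int), normalized=norm)
        np.testing.assert_array_equal(cv.embed_pca(ds, 5), cv.embed_pca(ds, 5))


class TestClusterGraph:
    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(6)
        blob1 = rng.normal(0, 1, (200, 5))
        blob2 = rng.normal(100, 1, (200, 5))
        emb = np.vstack([blob1, blob2])
        labels = cv.cluster_graph(emb, k_neighbors=15, resolution=0.3, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:200])) == 1 and len(set(labels[200:])) == 1
        # even at higher resolution no cell crosses the blob boundary
        labels_hi = cv.cluster_graph(emb, k_neighbors=15, resolution=0.5, seed=0)
        assert set(labels_hi[:200]).isdisjoint(set(labels_hi[200:]))

    def test_single_blob_low_resolution_one_cluster(self):
        rng = np.random.default_rng(7)
        emb = rng.normal(0, 1, (200, 5))
        labels = cv.cluster_graph(emb, k_neighbors=15, resolution=0.1, seed=0)
        assert len(set(labels)) == 1

    def test_largest_cluster_gets_label_zero(self):
        rng = np.random.default_rng(8)
        emb = np.vstack([rng.normal(0, 1, (150, 4)), rng.normal(50, 1, (60, 4))])
        labels = cv.cluster_graph(emb, k_neighbors=10, resolution=0.5, seed=0)
        sizes = np.bincount(labels)
        assert all(sizes[i] >= sizes[i + 1] for i in range(len(sizes) - 1))

    def test_cell_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(9)
        emb = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(60, 1, (80, 4))])
        labels = cv.cluster_graph(emb, k_neighbors=10, seed=0)
        perm = rng.permutation(len(emb))
        labels_p = cv.cluster_graph(emb[perm], k_neighbors=10, seed=0)
        # identical partition after undoing the permutation (up to relabeling,
        # but size-sorted relabeling makes the labels themselves equal)
        np.testing.assert_array_equal(labels[perm], labels_p)

    def test_too_few_cells_raises(self):
        with pytest.raises(cv.ContractError, match="k_neighbors"):
            cv.cluster_graph(np.zeros((5, 2)), k_neighbors=10)


class TestWilcoxon:
    def test_tied_example_exact_permutation_p(self):
        # in {3,4,5} vs out {0,0,1}: in-group ranks 4,5,6 sum to 15;
        # only 1 of C(6,3)=20 assignments reaches 15, two-sided p = 0.1
        assert exact_rank_sum_p(np.array([3.0, 4, 5]), np.array([0.0, 0, 1])) == pytest.approx(0.1)

    def test_tie_free_cases_match_scipy_exact(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n1, n2 = rng.integers(2, 9, size=2)
            pooled = rng.permutation(np.arange(n1 + n2, dtype=float))
            x, y = pooled[:n1], pooled[n1:]
            mine = exact_rank_sum_p(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_bh_matches_closed_form_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.002])
        # sorted: 0.002,0.01,0.03,0.04 -> step-up: min over j>=i of p_(j)*m/j
        expected_sorted = [0.008, 0.02, 0.04, 0.04]
        adj = bh_adjust(p)
        np.testing.assert_allclose(np.sort(adj), expected_sorted, rtol=1e-12)
        # monotone: adj_p non-decreasing in p
        order = np.argsort(p)
        assert all(np.diff(adj[order]) >= -1e-15)


class TestFindMarkers:
    def _marker_fixture(self):
        """Cluster 0 overexpresses g0; g1 is rarely detected in-cluster."""
        rng = np.random.default_rng(11)
        n = 40
        counts = rng.poisson(1.0, (2 * n, 4))
        counts[:, 3] += 1  # housekeeping gene keeps every cell's total > 0
        counts[:n, 0] += rng.poisson(5.0, n)  # strong marker of cluster 0
        counts[:n, 1] = 0
        counts[rng.choice(n, 2, replace=False), 1] = 8  # detected in 5% of cluster 0
        ds = cv.normalize_lognorm(make_dataset(counts))
        labels = np.array([0] * n + [1] * n)
        return ds, labels

    def test_low_fraction_gene_excluded_and_marker_found(self):
        ds, labels = self._marker_fixture()
        res = cv.find_markers(ds, labels)
        cluster0 = res[res["cluster"] == 0]
        assert "g0" in set(cluster0["gene"])
        assert "g1" not in set(cluster0["gene"])  # 5% detection < 10% floor

    def test_identical_distribution_gene_excluded(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(2.0, (60, 3))
        ds = cv.normalize_lognorm(make_dataset(counts))
        labels = np.array([0] * 30 + [1] * 30)
        res = cv.find_markers(ds, labels)
        # no gene differs between the groups; log fold changes are ~0
        assert len(res) == 0

    def test_retained_rows_satisfy_thresholds(self):
        ds, labels = self._marker_fixture()
        params = cv.MarkerTestParams()
        res = cv.find_markers(ds, labels, params)
        assert (res["logfc"] >= params.min_logfc).all()
        assert (res["adj_p"] <= params.max_adj_p).all()
        assert (res["fraction_in"] >= params.min_fraction).all()
        assert (res["adj_p"] >= res["p_value"] - 1e-15).all()

    def test_tiny_cluster_skipped_with_warning(self):
        ds = cv.normalize_lognorm(make_dataset(np.ones((10, 2), dtype=int)))
        labels = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            cv.find_markers(ds, labels)


class TestClusterDE:
    def test_overlapping_groups_rejected(self):
        ds = cv.normalize_lognorm(make_dataset(np.ones((9, 2), dtype=int)))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        with pytest.raises(cv.ContractError, match="overlap"):
            cv.cluster_de(ds, labels, {0, 1}, {1, 2})

    def test_single_cluster_vs_complement_matches_find_markers(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(1.0, (90, 6))
        counts[:30, 0] += rng.poisson(4.0, 30)
        counts[30:, 2] += rng.poisson(3.0, 60)
        ds = cv.normalize_lognorm(make_dataset(counts))
        labels = np.array([0] * 30 + [1] * 30 + [2] * 30)
        markers = cv.find_markers(ds, labels)
        m0 = markers[markers["cluster"] == 0].reset_index(drop=True)
        de = cv.cluster_de(ds, labels, {0}, {1, 2}, max_fdr=cv.MarkerTestParams().max_adj_p)
        assert list(de["gene"]) == list(m0["gene"])
        np.testing.assert_allclose(de["p_value"], m0["p_value"], rtol=1e-12)
        np.testing.assert_allclose(de["adj_p"], m0["adj_p"], rtol=1e-12)

    def test_recovery_of_upshifted_genes_with_fdr_control(self):
        rng = np.random.default_rng(14)
        n_cells, n_up, n_flat = 60, 50, 500
        base = rng.poisson(2.0, (2 * n_cells, n_up + n_flat))
        base[:n_cells, :n_up] = rng.poisson(4.0, (n_cells, n_up))  # 2x upshift
        ds = cv.normalize_lognorm(make_dataset(base))
        labels = np.array([0] * n_cells + [1] * n_cells)
        de = cv.cluster_de(ds, labels, {0}, {1}, max_fdr=0.05)
        up_genes = {f"g{j}" for j in range(n_up)}
        found = set(de["gene"])
        assert len(found & up_genes) >= 45
        assert len(found - up_genes) <= 0.05 * n_flat

    def test_permuted_labels_yield_near_empty_result(self):
        rng = np.random.default_rng(15)
        counts = rng.poisson(2.0, (120, 100))
        ds = cv.normalize_lognorm(make_dataset(counts))
        labels = rng.integers(0, 2, 120)
        de = cv.cluster_de(ds, labels, {0}, {1}, max_fdr=0.05)
        assert len(de) <= 5  # FDR-level false positives at most


def test_dotplot_stats_hand_fixture():
    counts = np.array([[2, 0], [1, 0], [0, 0], [0, 3]])
    norm = np.log1p(counts.astype(float))
    ds = make_dataset(counts, normalized=norm)
    labels = np.array([0, 0, 1, 1])
    stats_table = cv.dotplot_stats(ds, labels, ["g0", "g1"])
    t = stats_table.set_index(["gene", "cluster"])
    assert t.loc[("g0", 0), "fraction_expressing"] == 1.0
    assert t.loc[("g1", 0), "fraction_expressing"] == 0.0
    assert t.loc[("g1", 0), "mean_normalized"] == 0.0
    assert t.loc[("g0", 1), "fraction_expressing"] == 0.0
    assert t.loc[("g1", 1), "fraction_expressing"] == 0.5
    np.testing.assert_allclose(t.loc[("g0", 0), "mean_normalized"], np.log1p([2, 1]).mean())


def test_logfc_formula_is_expm1_mean_ratio():
    x_in, x_out = np.log1p(np.array([3.0, 5.0])), np.log1p(np.array([1.0, 1.0]))
    expected = np.log(4.0 + 1e-9) - np.log(1.0 + 1e-9)
    assert log_fold_change(x_in, x_out) == pytest.approx(expected, rel=1e-9)
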