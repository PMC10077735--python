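"""PCA conventions, SNN-Louvain behavior, correlation-distance silhouette,
resolution optimization, marker statistics and hypergeometric ORA."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from scpa import clustering, qc


def _norm_from_values(vals):
    vals = np.asarray(vals, dtype=float)
    gene_ids = np.array([f"G{i:04d}" for i in range(vals.shape[0])], dtype=object)
    cell_ids = np.array([f"c{i:04d}" for i in range(vals.shape[1])], dtype=object)
    params = pd.DataFrame({"nonzero": True}, index=pd.Index(gene_ids, name="gene"))
    return qc.NormalizedMatrix(vals, gene_ids, cell_ids, params, clip=np.inf)


def _blobs(rng, centers, n_per, sd=1.0, n_features=10):
    coords, labels = [], []
    for k, c in enumerate(centers):
        mean = np.zeros(n_features)
        mean[: len(c)] = c
        coords.append(rng.normal(mean, sd, size=(n_per, n_features)))
        labels += [k + 1] * n_per
    return np.vstack(coords), np.array(labels)


class TestRunPCA:
    def test_rank_two_data_has_two_informative_pcs(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 40))
        scores = rng.normal(size=(120, 2))
        vals = (scores @ basis).T  # genes x cells, rank 2
        emb = clustering.run_pca(_norm_from_values(vals), n_pcs=5)
        assert emb.explained_variance[1] > 1e-6
        np.testing.assert_allclose(emb.explained_variance[2:], 0.0, atol=1e-10)

    def test_deterministic_with_sign_convention(self, null_norm):
        e1 = clustering.run_pca(null_norm, 10)
        e2 = clustering.run_pca(null_norm, 10)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_explained_variance_decreasing(self, null_norm):
        emb = clustering.run_pca(null_norm, 15)
        assert (np.diff(emb.explained_variance) <= 1e-9).all()

    def test_bad_n_pcs(self, null_norm):
        with pytest.raises(ValueError):
            clustering.run_pca(null_norm, 0)

    def test_planted_cluster_centroid_separation(self, standard_study):
        emb = standard_study["emb"]
        labels = standard_study["true_labels"]
        coords = emb.coords[:, :4]
        centroids = np.array([coords[labels == c].mean(axis=0) for c in np.unique(labels)])
        within_sd = np.mean([coords[labels == c].std(axis=0).mean()
                             for c in np.unique(labels)])
        dists = [np.linalg.norm(a - b) for i, a in enumerate(centroids)
                 for b in centroids[i + 1:]]
        assert min(dists) > within_sd


class TestLouvain:
    def test_two_blob_recovery(self):
        rng = np.random.default_rng(1)
        coords, truth = _blobs(rng, [(0, 0), (20, 20)], 100)
        emb = clustering.Embedding(coords, np.ones(10), 10,
                                   np.array([f"c{i}" for i in range(200)], dtype=object))
        a = clustering.louvain_cluster(emb, k_neighbors=15, resolution=0.1, seed=0)
        assert a.n_clusters == 2
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_resolution_monotonicity_on_fixture(self):
        rng = np.random.default_rng(2)
        coords, _ = _blobs(rng, [(0, 0), (20, 20)], 100)
        emb = clustering.Embedding(coords, np.ones(10), 10,
                                   np.array([f"c{i}" for i in range(200)], dtype=object))
        k_lo = clustering.louvain_cluster(emb, 15, 0.1, seed=0).n_clusters
        k_hi = clustering.louvain_cluster(emb, 15, 5.0, seed=0).n_clusters
        assert k_hi >= k_lo

    def test_seed_invariance_on_separated_blobs(self):
        rng = np.random.default_rng(3)
        coords, _ = _blobs(rng, [(0, 0), (25, 25)], 80)
        emb = clustering.Embedding(coords, np.ones(10), 10,
                                   np.array([f"c{i}" for i in range(160)], dtype=object))
        a = clustering.louvain_cluster(emb, 15, 0.1, seed=0)
        b = clustering.louvain_cluster(emb, 15, 0.1, seed=999)
        assert adjusted_rand_score(a.labels, b.labels) == 1.0

    def test_labels_contiguous_by_size(self):
        rng = np.random.default_rng(4)
        coords, _ = _blobs(rng, [(0, 0), (25, 25)], 50)
        coords = np.vstack([coords, rng.normal((50, 50, 0, 0, 0, 0, 0, 0, 0, 0), 1.0,
                                               size=(150, 10))])
        emb = clustering.Embedding(coords, np.ones(10), 10,
                                   np.array([f"c{i}" for i in range(250)], dtype=object))
        a = clustering.louvain_cluster(emb, 15, 0.2, seed=0)
        sizes = [np.sum(a.labels == c) for c in range(1, a.n_clusters + 1)]
        assert sizes == sorted(sizes, reverse=True)
        assert set(a.labels) == set(range(1, a.n_clusters + 1))

    def test_too_few_cells(self):
        emb = clustering.Embedding(np.zeros((5, 3)), np.ones(3), 3,
                                   np.array(list("abcde"), dtype=object))
        with pytest.raises(ValueError):
            clustering.louvain_cluster(emb, k_neighbors=10)


class TestSilhouetteCorrelation:
    def _fixture(self, seed=5, n=250):
        rng = np.random.default_rng(seed)
        coords, truth = _blobs(rng, [(5, 0, -5), (0, 5, 5)], n, sd=0.5, n_features=6)
        return coords, truth

    def test_correct_labels_high(self):
        coords, truth = self._fixture()
        assert clustering.silhouette_correlation(coords, truth) > 0.9

    def test_random_labels_near_zero(self):
        coords, truth = self._fixture()
        rng = np.random.default_rng(6)
        assert abs(clustering.silhouette_correlation(coords, rng.permutation(truth))) < 0.1

    def test_cross_assigned_points_score_negative(self):
        # silhouette is invariant to relabeling a partition, so a full swap
        # changes nothing; points individually assigned to the wrong blob,
        # however, must get negative widths and drag the mean down
        from sklearn.metrics import silhouette_samples

        from scpa.clustering import _correlation_distances

        coords, truth = self._fixture()
        assert clustering.silhouette_correlation(coords, 3 - truth) == pytest.approx(
            clustering.silhouette_correlation(coords, truth)
        )
        labels = truth.copy()
        swapped = np.concatenate([np.flatnonzero(truth == 1)[:25],
                                  np.flatnonzero(truth == 2)[:25]])
        labels[swapped] = 3 - labels[swapped]
        widths = silhouette_samples(_correlation_distances(coords), labels,
                                    metric="precomputed")
        assert (widths[swapped] < 0).all()
        assert clustering.silhouette_correlation(coords, labels) < \
            clustering.silhouette_correlation(coords, truth)

    def test_single_cluster_rejected(self):
        coords, truth = self._fixture()
        with pytest.raises(ValueError):
            clustering.silhouette_correlation(coords, np.ones_like(truth))

    def test_invariant_to_positive_affine_rescaling(self):
        coords, truth = self._fixture()
        rng = np.random.default_rng(7)
        scale = rng.uniform(0.5, 3.0, size=(coords.shape[0], 1))
        shift = rng.uniform(-2, 2, size=(coords.shape[0], 1))
        s1 = clustering.silhouette_correlation(coords, truth)
        s2 = clustering.silhouette_correlation(coords * scale + shift, truth)
        assert abs(s1 - s2) < 1e-9


class TestOptimizeResolution:
    def test_grid_bounds_enforced(self, null_norm):
        emb = clustering.run_pca(null_norm, 5)
        with pytest.raises(ValueError):
            clustering.optimize_resolution(emb, grid=np.array([0.001, 0.5]), n_repeats=1)

    def test_default_grid_spans_paper_range(self):
        g = clustering.DEFAULT_RESOLUTION_GRID
        assert g.min() == 0.01 and g.max() == 1.0 and len(g) == 25

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        coords, _ = _blobs(rng, [(0, 0), (12, 12), (-12, 12)], 60)
        emb = clustering.Embedding(coords, np.ones(10), 10,
                                   np.array([f"c{i}" for i in range(180)], dtype=object))
        grid = np.array([0.05, 0.3, 0.8])
        a = clustering.optimize_resolution(emb, grid=grid, n_repeats=5, subsample=120, seed=3)
        b = clustering.optimize_resolution(emb, grid=grid, n_repeats=5, subsample=120, seed=3)
        assert a.resolution == b.resolution
        np.testing.assert_array_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.silhouette_trace, b.silhouette_trace)

    def test_trace_covers_grid(self):
        rng = np.random.default_rng(9)
        coords, _ = _blobs(rng, [(0, 0), (15, 15)], 60)
        emb = clustering.Embedding(coords, np.ones(10), 10,
                                   np.array([f"c{i}" for i in range(120)], dtype=object))
        grid = np.array([0.05, 0.5, 1.0])
        a = clustering.optimize_resolution(emb, grid=grid, n_repeats=3, subsample=100, seed=0)
        np.testing.assert_array_equal(a.silhouette_trace["resolution"], grid)


class TestFindMarkers:
    def test_exclusive_gene_is_top_marker(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(50, 120))
        vals[7, :60] += 4.0  # gene G0007 high only in cluster 1
        norm = _norm_from_values(vals)
        labels = np.array([1] * 60 + [2] * 60)
        table = clustering.find_markers(norm, labels)
        c1 = table[table["cluster"] == 1].sort_values("p")
        assert c1.iloc[0]["gene"] == "G0007"
        assert c1.iloc[0]["p_adj_bonferroni"] < 0.05

    def test_null_fpr_controlled(self, null_norm):
        labels = np.array([1] * 100 + [2] * 100)
        table = clustering.find_markers(null_norm, labels)
        sub = table[table["cluster"] == 1]
        fpr = (sub["p"] < 0.05).mean()
        assert fpr <= 0.07
        assert stats.kstest(sub["p"], "uniform").pvalue > 0.01

    def test_bonferroni_definition(self, null_norm):
        labels = np.array([1] * 100 + [2] * 100)
        table = clustering.find_markers(null_norm, labels)
        n_tests = len(table)
        np.testing.assert_allclose(
            table["p_adj_bonferroni"], np.minimum(1.0, table["p"] * n_tests)
        )
        assert (table["p_adj_bonferroni"] >= table["p"] - 1e-15).all()

    def test_single_cluster_rejected(self, null_norm):
        with pytest.raises(ValueError):
            clustering.find_markers(null_norm, np.ones(null_norm.values.shape[1]))


class TestORA:
    def test_exact_hypergeometric_closed_form(self):
        universe = [f"G{i}" for i in range(50)]
        gene_list = universe[:5]
        sets = {"hit": set(universe[:5]), "half": set(universe[:10])}
        table = clustering.ora_enrichment(gene_list, sets, universe).set_index("set")
        # full-overlap set of size 5 drawn from 50: upper-tail P(X >= 5)
        expected = stats.hypergeom.sf(4, 50, 5, 5)
        assert table.loc["hit", "p_hypergeometric"] == pytest.approx(expected, rel=1e-12)
        assert table.loc["hit", "p_hypergeometric"] == pytest.approx(1 / 2118760, rel=1e-9)

    def test_disjoint_set_near_one(self):
        universe = [f"G{i}" for i in range(100)]
        table = clustering.ora_enrichment(
            universe[:3], {"far": set(universe[50:55])}, universe
        )
        assert table["p_hypergeometric"].iloc[0] >= 0.5

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            clustering.ora_enrichment(["X"], {"s": {"A"}}, ["A", "B"])

    def test_top_marker_default_is_50(self, null_norm):
        labels = np.array([1] * 100 + [2] * 100)
        table = clustering.find_markers(null_norm, labels)
        top = clustering.top_markers(table)
        assert all(len(v) == 50 for v in top.values())


def test_elbow_detector_on_synthetic_scree():
    ev = np.concatenate([np.array([100, 60, 30, 15]), np.full(16, 1.0)])
    k = clustering.elbow_n_pcs(ev)
    assert 2 <= k <= 6
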