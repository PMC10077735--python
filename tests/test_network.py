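"""metaCell pooling conservation, adaptive-partition MI properties against
the binned and permutation oracles, DPI versus brute-force triangle
enumeration, and consensus-network behavior."""
import itertools

import numpy as np
import pytest
from scipy import stats

from scpa import clustering, network, qc, synthetic


class TestPoolMetacells:
    @pytest.fixture()
    def pooled(self, small_dataset):
        gem, bundle = small_dataset
        norm = qc.normalize_pearson_residuals(gem)
        qc.select_hvg(norm, gem.n_genes)
        emb = clustering.run_pca(norm, 10)
        meta = network.pool_metacells(gem, bundle.cell_labels, emb, n_meta=30, k=4, seed=2)
        return gem, meta

    def test_counts_conserved(self, pooled):
        gem, meta = pooled
        dense = gem.to_dense()
        for j, members in enumerate(meta.members):
            np.testing.assert_array_equal(meta.raw[:, j], dense[:, members].sum(axis=1))

    def test_members_stay_in_origin_cluster(self, small_dataset):
        gem, bundle = small_dataset
        norm = qc.normalize_pearson_residuals(gem)
        emb = clustering.run_pca(norm, 10)
        meta = network.pool_metacells(gem, bundle.cell_labels, emb, n_meta=30, k=4, seed=2)
        for j, members in enumerate(meta.members):
            assert all(bundle.cell_labels[m] == meta.origin_cluster[j] for m in members)

    def test_min_rule_small_cluster(self, small_dataset):
        gem, bundle = small_dataset
        norm = qc.normalize_pearson_residuals(gem)
        emb = clustering.run_pca(norm, 10)
        meta = network.pool_metacells(gem, bundle.cell_labels, emb, n_meta=250, k=4, seed=2)
        # both clusters have 60 cells: min(250, 60) each
        assert meta.n_metacells == 120

    def test_k1_is_identity_pooling(self, small_dataset):
        gem, bundle = small_dataset
        norm = qc.normalize_pearson_residuals(gem)
        emb = clustering.run_pca(norm, 10)
        meta = network.pool_metacells(gem, bundle.cell_labels, emb, n_meta=500, k=1, seed=2)
        dense = gem.to_dense()
        for j, members in enumerate(meta.members):
            assert len(members) == 1
            np.testing.assert_array_equal(meta.raw[:, j], dense[:, members[0]])

    def test_log2cpm_scaling(self, pooled):
        _, meta = pooled
        lib = meta.raw.sum(axis=0)
        expected = np.log2(meta.raw / lib * 1e6 + 1.0)
        np.testing.assert_allclose(meta.values, expected)


class TestEstimateMI:
    def test_nonnegative_and_zero_for_constant(self, rng):
        x = rng.normal(size=100)
        with pytest.warns(UserWarning, match="constant"):
            assert network.estimate_mi(x, np.ones(100)) == 0.0
        assert network.estimate_mi(x, rng.normal(size=100)) >= 0.0

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=400)
        y = 0.7 * x + rng.normal(size=400)
        base = network.estimate_mi(x, y)
        assert network.estimate_mi(np.exp(x), y) == pytest.approx(base)
        assert network.estimate_mi(x, np.log(y - y.min() + 1)) == pytest.approx(base)

    def test_rank_reflection_symmetry_power_of_two(self, rng):
        # midpoint splits stay integral when n is a power of two, making the
        # partition exactly mirror-symmetric under y -> -y
        x = rng.normal(size=512)
        assert network.estimate_mi(x, -x) == pytest.approx(network.estimate_mi(x, x))

    def test_independent_below_permutation_null_95th(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        observed = network.estimate_mi(x, y)
        null = [network.estimate_mi(x, np.random.default_rng(i).permutation(y), seed=i)
                for i in range(200)]
        assert observed <= np.quantile(null, 0.95)

    def test_matches_binned_oracle_on_dependent_pairs(self, rng):
        for rho in (0.9, 0.95):
            x = rng.normal(size=1000)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=1000)
            adaptive = network.estimate_mi(x, y)
            oracle = network.estimate_mi(x, y, method="equal_freq_bins")
            assert adaptive == pytest.approx(oracle, rel=0.10)

    def test_identity_matches_fine_binned_oracle(self, rng):
        x = rng.normal(size=500)
        adaptive = network.estimate_mi(x, x)
        oracle = network.estimate_mi(x, x, method="equal_freq_bins", bins=100)
        assert adaptive == pytest.approx(oracle, rel=0.10)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            network.estimate_mi(np.arange(5.0), np.arange(5.0))


class TestMiNullThreshold:
    @pytest.fixture(scope="class")
    def null_meta(self):
        r = np.random.default_rng(33)
        vals = r.normal(size=(150, 300))
        return network.MetaCellMatrix(
            vals, np.abs(vals), np.array([f"G{i}" for i in range(150)], dtype=object),
            np.ones(300, dtype=int), [[i] for i in range(300)], 1,
        )

    def test_median_at_p_half(self, null_meta):
        thr = network.mi_null_threshold(null_meta, n_null_pairs=600, p_threshold=0.5, seed=1)
        r = np.random.default_rng(1)
        # independent re-estimate of the null median
        null = []
        for i in range(400):
            gi, gj = r.integers(0, 150, size=2)
            x, y = null_meta.values[gi], np.random.default_rng(i).permutation(null_meta.values[gj])
            null.append(network.estimate_mi(x, y, seed=i))
        med = np.median(null)
        assert thr == pytest.approx(med, rel=0.10, abs=0.002)

    def test_monotone_in_p_threshold(self, null_meta):
        thrs = [network.mi_null_threshold(null_meta, n_null_pairs=600, p_threshold=p, seed=1)
                for p in (1e-2, 1e-4, 1e-8)]
        assert thrs[0] < thrs[1] < thrs[2]

    def test_false_positive_calibration_at_1e3(self, null_meta):
        # on pure-null data, the fraction of random pairs above the p=1e-3
        # threshold should be ~1e-3 (Poisson 95% band around n_pairs * p)
        thr = network.mi_null_threshold(null_meta, n_null_pairs=2000, p_threshold=1e-3, seed=5)
        r = np.random.default_rng(6)
        n_pairs = 4000
        passing = 0
        for i in range(n_pairs):
            gi, gj = r.choice(150, size=2, replace=False)
            y = r.permutation(null_meta.values[gj])
            passing += network.estimate_mi(null_meta.values[gi], y, seed=i) >= thr
        lo, hi = stats.poisson.ppf([0.025, 0.975], n_pairs * 1e-3)
        assert lo <= passing <= hi

    def test_too_few_pairs_rejected(self, null_meta):
        with pytest.raises(ValueError):
            network.mi_null_threshold(null_meta, n_null_pairs=50)


def _brute_force_dpi(edges, tolerance=0.0):
    mi = {}
    for a, b, m in edges:
        mi[frozenset((a, b))] = m
    removed = set()
    for (a, b, m_ab) in edges:
        for c in {n for e in mi for n in e} - {a, b}:
            e1, e2 = frozenset((a, c)), frozenset((b, c))
            if e1 in mi and e2 in mi:
                if m_ab < min(mi[e1], mi[e2]) * (1 - tolerance):
                    removed.add(frozenset((a, b)))
    return [e for e in edges if frozenset((e[0], e[1])) not in removed]


class TestDPI:
    def test_triangle_weakest_removed(self):
        edges = [("a", "b", 3.0), ("b", "c", 2.0), ("a", "c", 1.0)]
        kept = network.apply_dpi(edges)
        assert ("a", "c", 1.0) not in kept and len(kept) == 2

    def test_chain_untouched(self):
        edges = [("a", "b", 3.0), ("b", "c", 2.0)]
        assert network.apply_dpi(edges) == edges

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(20)]
        for rep in range(50):
            pairs = list(itertools.combinations(nodes, 2))
            chosen = rng.choice(len(pairs), size=60, replace=False)
            edges = [(*pairs[i], float(rng.uniform(0.1, 5.0))) for i in chosen]
            assert set(network.apply_dpi(edges)) == set(_brute_force_dpi(edges))

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(15)]
        pairs = list(itertools.combinations(nodes, 2))
        chosen = rng.choice(len(pairs), size=50, replace=False)
        edges = [(*pairs[i], float(rng.uniform(0.1, 5.0))) for i in chosen]
        once = network.apply_dpi(edges)
        assert set(once) <= set(edges)
        assert network.apply_dpi(once) == once

    def test_tolerance_keeps_near_ties(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 0.95)]
        assert len(network.apply_dpi(edges, tolerance=0.0)) == 2
        assert len(network.apply_dpi(edges, tolerance=0.10)) == 3


class TestConsensusNetwork:
    @pytest.fixture(scope="class")
    def planted(self):
        truth = synthetic.generate_truth_network(400, 6, 15, pos_fraction=0.5, seed=5,
                                                 strength_range=(1.0, 2.0))
        gem, _ = synthetic.simulate_sc_counts(truth, np.zeros((6, 1)), [600],
                                              activity_sd=1.5, seed=5)
        norm = qc.normalize_pearson_residuals(gem)
        qc.select_hvg(norm, 400)
        emb = clustering.run_pca(norm, 10)
        meta = network.pool_metacells(gem, np.ones(600, dtype=int), emb,
                                      n_meta=300, k=3, seed=0)
        return truth, meta

    def test_default_bootstraps_is_100(self):
        import inspect

        sig = inspect.signature(network.bootstrap_consensus_network)
        assert sig.parameters["n_boot"].default == 100

    def test_recovers_planted_edges(self, planted):
        truth, meta = planted
        net = network.bootstrap_consensus_network(meta, truth.regulators, n_boot=20,
                                                  p_threshold=1e-4, seed=2)
        te = {tuple(sorted(e)) for e in truth.edge_set()}
        rec = {tuple(sorted((a, b))) for a, b in zip(net.edge_table["a"], net.edge_table["b"])}
        tp = len(rec & te)
        assert tp / len(te) > 0.4           # recall well above chance
        assert tp / max(len(rec), 1) > 0.7  # high precision

    def test_thresholded_edges_shrink_with_stricter_threshold(self, planted):
        # the MI-thresholded edge set is exactly nested across p-thresholds;
        # the bootstrap consensus on top is not monotone (a lenient threshold
        # floods bootstraps with noise edges and raises the Poisson bar)
        truth, meta = planted
        from scpa.network import _deterministic_ranks, _mi_pairs, _candidate_pairs

        gidx = {g: i for i, g in enumerate(meta.gene_ids)}
        present = [r for r in truth.regulators if r in gidx]
        ri, ti = _candidate_pairs(meta.gene_ids, present)
        ranks = _deterministic_ranks(meta.values, seed=0)
        mi = _mi_pairs(ranks, ri, ti)
        thrs = [network.mi_null_threshold(meta, n_null_pairs=500, p_threshold=p, seed=1)
                for p in (1e-2, 1e-4, 1e-6)]
        counts = [(mi >= t).sum() for t in thrs]
        assert thrs[0] <= thrs[1] <= thrs[2]
        assert counts[0] >= counts[1] >= counts[2]

    def test_regulator_classes_unioned(self, planted):
        truth, meta = planted
        classes = {"tf": truth.regulators[:3], "sig": truth.regulators[3:]}
        both = network.bootstrap_consensus_network(meta, classes, n_boot=10,
                                                   p_threshold=1e-4, seed=2)
        # each class is run separately and the edge sets are unioned, so
        # regulators from both classes must contribute edges
        touched = set(both.edge_table["a"]) | set(both.edge_table["b"])
        assert touched & set(classes["tf"])
        assert touched & set(classes["sig"])

    def test_too_few_metacells_rejected(self, planted):
        truth, meta = planted
        tiny = network.MetaCellMatrix(meta.values[:, :5], meta.raw[:, :5], meta.gene_ids,
                                      meta.origin_cluster[:5], meta.members[:5], meta.k)
        with pytest.raises(ValueError, match="metacells"):
            network.bootstrap_consensus_network(tiny, truth.regulators)


class TestBuildRegulons:
    def test_likelihood_normalized_and_signs(self, regulon_recovery_study):
        truth = regulon_recovery_study["truth"]
        net = regulon_recovery_study["net"]
        sign_truth = {(r, t): s for r, t, s, w in truth.edges}
        strengths = {(r, t): w for r, t, s, w in truth.edges}
        correct = total = 0
        for reg in net.regulons:
            assert reg.likelihood.max() == pytest.approx(1.0)
            assert len(set(reg.targets)) == len(reg.targets)
            assert reg.regulator not in reg.targets
            assert reg.size <= 50
            for t, m in zip(reg.targets, reg.tfmode):
                key = (reg.regulator, t)
                if key in sign_truth and strengths[key] >= 1.3:
                    total += 1
                    correct += np.sign(m) == sign_truth[key]
        assert total > 100
        assert correct / total >= 0.9

    def test_roundtrip_tsv(self, tmp_path, regulon_recovery_study):
        regs = regulon_recovery_study["net"].regulons
        path = tmp_path / "regulons.tsv"
        network.write_regulons(regs, path)
        back = network.read_regulons(path)
        assert [r.regulator for r in back] == sorted(r.regulator for r in regs)
        orig = {r.regulator: r for r in regs}
        for r in back:
            assert r.targets == orig[r.regulator].targets
            np.testing.assert_allclose(r.tfmode, orig[r.regulator].tfmode)
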