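"""Shared fixtures.

Two session-scoped "study" fixtures carry the expensive simulations used by
the acceptance-level tests: a single-population regulon-recovery study and
the standard five-cluster pipeline study (1000 genes, 25 regulators,
5 planted clusters, 200 cells/cluster).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from scpa import clustering, network, qc, synthetic, viper

warnings.filterwarnings("ignore", category=UserWarning)


def log2_cpm(gem):
    lib = np.asarray(gem.counts.sum(axis=0)).ravel()
    return np.log2(gem.to_dense() / np.maximum(lib, 1) * 1e6 + 1.0)


@pytest.fixture(scope="session")
def small_truth():
    return synthetic.generate_truth_network(
        n_genes=600, n_regulators=5, regulon_size=10, pos_fraction=0.7, seed=42
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    activities = synthetic.default_cluster_activities(5, 2, magnitude=1.8, seed=42)
    gem, bundle = synthetic.simulate_sc_counts(
        small_truth, activities, [60, 60], activity_sd=0.5, seed=42
    )
    return gem, bundle


@pytest.fixture(scope="session")
def regulon_recovery_study():
    """Planted single-population network: 25 regulators x 40 targets,
    800 KNN-pooled metacells, 100-bootstrap consensus."""
    truth = synthetic.generate_truth_network(
        n_genes=4000, n_regulators=25, regulon_size=40, pos_fraction=0.5,
        seed=11, strength_range=(1.0, 2.0),
    )
    # library scaled with the universe so per-gene depth matches the
    # standard scale while the planted targets stay a modest fraction
    # of the transcriptome
    gem, bundle = synthetic.simulate_sc_counts(
        truth, np.zeros((25, 1)), [4000], activity_sd=1.5, seed=11,
        lib_size_lognormal=(np.log(3200.0), 0.12),
    )
    norm = qc.normalize_pearson_residuals(gem)
    qc.select_hvg(norm, truth.n_genes)
    emb = clustering.run_pca(norm, 20)
    meta = network.pool_metacells(
        gem, np.ones(gem.n_cells, dtype=int), emb, n_meta=800, k=5, seed=0
    )
    net = network.bootstrap_consensus_network(
        meta, truth.regulators, n_boot=100, seed=3, context_id="matched"
    )
    network.build_regulons(net, meta, max_targets=50, min_targets=10,
                           regulators=truth.regulators)
    return {"truth": truth, "bundle": bundle, "meta": meta, "net": net}


@pytest.fixture(scope="session")
def standard_study():
    """Five planted clusters through the whole single-cell side of the
    pipeline: QC, normalization, silhouette-optimized expression clustering,
    per-cluster networks, metaVIPER activity, activity re-clustering, MRs."""
    truth = synthetic.generate_truth_network(
        n_genes=1000, n_regulators=25, regulon_size=40, pos_fraction=0.5, seed=7
    )
    act = synthetic.default_cluster_activities(25, 5, magnitude=1.8, seed=7)
    gem, bundle = synthetic.simulate_sc_counts(
        truth, act, [200] * 5, activity_sd=0.8, seed=7
    )
    filt, _ = qc.filter_cells(gem)
    keep = np.isin(gem.cell_ids, filt.cell_ids)
    true_labels = bundle.cell_labels[keep]
    cell_activities = bundle.cell_activities[keep]
    norm = qc.normalize_pearson_residuals(filt)
    qc.select_hvg(norm, 1000)
    emb = clustering.run_pca(norm, 30)
    expr_assign = clustering.optimize_resolution(emb, n_repeats=100, subsample=500, seed=1)

    networks = []
    for c in np.unique(expr_assign.labels):
        mask = expr_assign.labels == c
        sub = filt.subset_cells(mask)
        sub_emb = clustering.Embedding(
            emb.coords[mask], emb.explained_variance, emb.n_pcs, emb.cell_ids[mask]
        )
        meta = network.pool_metacells(
            sub, np.ones(sub.n_cells, dtype=int), sub_emb, n_meta=250, k=10, seed=int(c)
        )
        net = network.bootstrap_consensus_network(
            meta, truth.regulators, n_boot=100, p_threshold=1e-4,
            seed=int(c) + 10, context_id=f"cluster{c}",
        )
        if net.edge_table.empty:
            continue
        network.build_regulons(net, meta, max_targets=50, min_targets=10,
                               regulators=truth.regulators)
        if net.regulons:
            networks.append(net)

    sig = viper.compute_signatures(log2_cpm(filt), filt.gene_ids, filt.cell_ids)
    activity = viper.metaviper_activity(sig, networks, min_targets=10)
    act_emb = clustering.run_pca(viper.activity_to_norm(activity), 15)
    act_assign = clustering.optimize_resolution(act_emb, n_repeats=100, subsample=500, seed=2)
    mr = viper.master_regulators(activity, act_assign.labels, n_boot=100, seed=3)
    return {
        "truth": truth,
        "bundle": bundle,
        "cluster_activities": act,
        "gem": gem,
        "filt": filt,
        "true_labels": true_labels,
        "cell_activities": cell_activities,
        "norm": norm,
        "emb": emb,
        "expr_assign": expr_assign,
        "networks": networks,
        "signatures": sig,
        "activity": activity,
        "act_assign": act_assign,
        "mr": mr,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def null_norm():
    """Gaussian 'normalized' matrix with no structure: 1000 genes x 200 cells."""
    r = np.random.default_rng(123)
    vals = r.normal(size=(1000, 200))
    gene_ids = np.array([f"G{i:04d}" for i in range(1000)], dtype=object)
    cell_ids = np.array([f"c{i:03d}" for i in range(200)], dtype=object)
    params = pd.DataFrame({"nonzero": True}, index=pd.Index(gene_ids, name="gene"))
    return qc.NormalizedMatrix(vals, gene_ids, cell_ids, params, clip=np.inf)
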