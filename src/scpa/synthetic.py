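"""Synthetic single-cell and bulk count data with a planted regulatory network.

The generator plants a known regulator->target network, cluster-specific
latent regulator activities and a two-group bulk cohort whose differential
expression is driven by shifting a designated regulator program.  Every
downstream stage of the pipeline (QC, clustering, network inference, activity
inference, master regulators, DEG/GSEA) can then be tested by recovery
against the returned ground truth.

Count model: per-cell gene means are log-linear in latent regulator activity;
overdispersion comes from multiplicative Gamma noise (Gamma-Poisson = negative
binomial) and counts are multinomially thinned to an exactly controlled
LogNormal library size, so column sums equal drawn library sizes exactly.

The first 20 gene ids carry the "MT-" prefix (10x convention) so that
percent-mitochondrial QC is computable by name.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import GeneExpressionMatrix

N_MITO_GENES = 20

QC_RULES = ("low_umi", "high_mito", "low_genes", "high_genes", "low_complexity")


@dataclass
class TruthNetwork:
    """Planted regulatory network: the object network inference must recover."""

    regulators: list[str]
    # (regulator, target, sign in {-1,+1}, strength > 0)
    edges: list[tuple[str, str, int, float]]
    regulon_size: int
    n_genes: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        for reg, tgt, sign, strength in self.edges:
            if genes and tgt not in genes:
                raise ValueError(f"edge target {tgt!r} is not a valid gene id")
            if reg == tgt:
                raise ValueError(f"self-edge on {reg!r}")
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be +/-1, got {sign}")
            if strength <= 0:
                raise ValueError("edge strength must be positive")
        with_targets = {e[0] for e in self.edges}
        if set(self.regulators) - with_targets:
            raise ValueError("every regulator needs at least one target")

    def targets_of(self, regulator: str) -> list[tuple[str, int, float]]:
        return [(t, s, w) for r, t, s, w in self.edges if r == regulator]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _, _ in self.edges}


@dataclass
class TruthBundle:
    """Ground truth handed to the test surface, never to the pipeline."""

    network: TruthNetwork
    cluster_activities: np.ndarray        # regulators x clusters
    cell_labels: np.ndarray               # cell -> 1-based cluster id
    bulk_effects: dict[str, float]        # regulator -> activity shift in disease
    seed: int
    cell_activities: np.ndarray | None = None  # cells x regulators, realized latents

    def __post_init__(self) -> None:
        if self.cluster_activities.shape[0] != len(self.network.regulators):
            raise ValueError("cluster_activities rows must match regulators")
        n_clusters = self.cluster_activities.shape[1]
        labels = np.asarray(self.cell_labels)
        if labels.size and (labels.min() < 1 or labels.max() > n_clusters):
            raise ValueError("cell labels must index planted clusters (1-based)")


def make_gene_ids(n_genes: int) -> list[str]:
    """First 20 ids are mitochondrial ("MT-"), the rest G####."""
    if n_genes <= N_MITO_GENES:
        raise ValueError(f"need more than {N_MITO_GENES} genes")
    width = max(4, len(str(n_genes)))
    ids = [f"MT-{i + 1}" for i in range(N_MITO_GENES)]
    ids += [f"G{i + 1:0{width}d}" for i in range(N_MITO_GENES, n_genes)]
    return ids


def generate_truth_network(
    n_genes: int,
    n_regulators: int,
    regulon_size: int,
    pos_fraction: float = 0.7,
    seed: int = 0,
    strength_range: tuple[float, float] = (0.5, 1.5),
    allow_regulator_targets: bool = False,
) -> TruthNetwork:
    """Plant ``n_regulators`` regulons of exactly ``regulon_size`` distinct targets.

    Signs are +1 with probability ``pos_fraction``; strengths are uniform on
    ``strength_range``.  Deterministic given ``seed``.

    By default targets are drawn outside the regulator set, so the planted
    programs stay statistically independent: cascaded regulation creates
    indirect regulator-target dependence through shared upstream drivers,
    which no pairwise-MI method can fully separate from direct edges.  Set
    ``allow_regulator_targets`` to plant such cascades deliberately.
    """
    if not 0.0 <= pos_fraction <= 1.0:
        raise ValueError("pos_fraction must be in [0, 1]")
    if n_regulators > n_genes:
        raise ValueError("cannot have more regulators than genes")
    gene_ids = make_gene_ids(n_genes)
    non_mito = gene_ids[N_MITO_GENES:]
    if n_regulators > len(non_mito):
        raise ValueError("not enough non-mitochondrial genes for regulators")
    if regulon_size > len(non_mito) - 1:
        raise ValueError("regulon_size too large for the gene universe")
    rng = np.random.default_rng(seed)
    regulators = list(rng.choice(non_mito, size=n_regulators, replace=False))
    reg_set = set(regulators)
    if not allow_regulator_targets and regulon_size > len(non_mito) - len(reg_set):
        raise ValueError("regulon_size too large once regulators are excluded as targets")
    edges: list[tuple[str, str, int, float]] = []
    for reg in regulators:
        if allow_regulator_targets:
            candidates = [g for g in non_mito if g != reg]
        else:
            candidates = [g for g in non_mito if g not in reg_set]
        targets = rng.choice(candidates, size=regulon_size, replace=False)
        signs = np.where(rng.random(regulon_size) < pos_fraction, 1, -1)
        strengths = rng.uniform(*strength_range, size=regulon_size)
        for tgt, sign, strength in zip(targets, signs, strengths):
            edges.append((reg, str(tgt), int(sign), float(strength)))
    return TruthNetwork(
        regulators=regulators,
        edges=edges,
        regulon_size=regulon_size,
        n_genes=n_genes,
        gene_ids=gene_ids,
    )


def _base_log2_abundance(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    # relative log2 abundance across genes; the spread is kept moderate so a
    # desk-scale gene universe still yields realistic per-cell gene diversity
    return rng.normal(loc=0.0, scale=0.8, size=n_genes)


def default_cluster_activities(
    n_regulators: int,
    n_clusters: int,
    magnitude: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Sparse planted program: each regulator active in exactly one cluster.

    Regulators are dealt round-robin across clusters with activity
    +/-``magnitude`` (random sign), so every cluster is driven by a distinct
    regulator program of ~n_regulators/n_clusters members.
    """
    rng = np.random.default_rng(seed)
    act = np.zeros((n_regulators, n_clusters))
    for p in range(n_regulators):
        act[p, p % n_clusters] = rng.choice([-magnitude, magnitude])
    return act


def _gene_log2_shift(
    truth: TruthNetwork, activity: dict[str, float], gene_index: dict[str, int]
) -> np.ndarray:
    """Additive log2-mean shift per gene induced by regulator activities.

    Regulator genes track their own activity (coefficient 1); targets move by
    sign * strength * activity, summed over incoming edges.
    """
    shift = np.zeros(len(gene_index))
    for reg, act in activity.items():
        if act == 0.0:
            continue
        shift[gene_index[reg]] += act
        for tgt, sign, strength in truth.targets_of(reg):
            shift[gene_index[tgt]] += sign * strength * act
    return shift


def simulate_sc_counts(
    truth: TruthNetwork,
    activities: np.ndarray,
    cells_per_cluster: list[int] | np.ndarray,
    lib_size_lognormal: tuple[float, float] = (np.log(1600.0), 0.12),
    nb_dispersion: float = 0.2,
    mito_fraction: float | np.ndarray = 0.02,
    qc_violators: dict[str, list[int]] | None = None,
    activity_sd: float = 0.5,
    n_samples: int = 2,
    seed: int = 0,
) -> tuple[GeneExpressionMatrix, TruthBundle]:
    """Draw a UMI count matrix with planted cluster structure.

    ``activities`` is regulators x clusters; each cell's latent activity is its
    cluster's value plus N(0, activity_sd) cell-level jitter, so regulator and
    target expression co-vary within clusters as well as across them.

    ``qc_violators`` maps a QC rule name ("low_umi", "high_mito", "low_genes",
    "high_genes", "low_complexity") to the cell indices forced to violate it.
    """
    activities = np.atleast_2d(np.asarray(activities, dtype=float))
    if activities.shape[0] != len(truth.regulators):
        raise ValueError("activities must have one row per regulator")
    cells_per_cluster = np.asarray(cells_per_cluster, dtype=int)
    if activities.shape[1] != len(cells_per_cluster):
        raise ValueError("activities must have one column per cluster")
    if (cells_per_cluster < 1).any():
        raise ValueError("every cluster needs at least one cell")
    qc_violators = qc_violators or {}
    for rule in qc_violators:
        if rule not in QC_RULES:
            raise ValueError(f"unknown QC rule {rule!r}; known: {QC_RULES}")

    rng = np.random.default_rng(seed)
    n_genes = truth.n_genes
    gene_ids = truth.gene_ids
    gidx = {g: i for i, g in enumerate(gene_ids)}
    mito = np.arange(N_MITO_GENES)
    n_cells = int(cells_per_cluster.sum())
    labels = np.repeat(np.arange(1, len(cells_per_cluster) + 1), cells_per_cluster)

    base = _base_log2_abundance(n_genes, rng)
    # per-gene shift coefficients: column p holds the log2 response to a unit
    # of regulator p's activity
    coef = np.zeros((n_genes, len(truth.regulators)))
    for p, reg in enumerate(truth.regulators):
        unit = _gene_log2_shift(truth, {reg: 1.0}, gidx)
        coef[:, p] = unit

    mito_frac = np.broadcast_to(np.asarray(mito_fraction, dtype=float), (n_cells,)).copy()
    lib_mu, lib_sigma = lib_size_lognormal
    lib_sizes = np.maximum(
        np.round(rng.lognormal(lib_mu, lib_sigma, size=n_cells)).astype(int), 10
    )

    for idx in qc_violators.get("low_umi", []):
        lib_sizes[idx] = int(rng.integers(100, 1000))
    for idx in qc_violators.get("high_mito", []):
        mito_frac[idx] = 0.15
    restricted: dict[int, int] = {}
    for idx in qc_violators.get("low_genes", []):
        restricted[idx] = 150            # < 300 expressed genes
        lib_sizes[idx] = max(lib_sizes[idx], 2000)
    for idx in qc_violators.get("low_complexity", []):
        restricted[idx] = 15             # log10(15)/log10(lib) << 0.8
        lib_sizes[idx] = max(lib_sizes[idx], 5000)
    for idx in qc_violators.get("high_genes", []):
        if n_genes <= 8000:
            raise ValueError("high_genes violators need a matrix with >8000 genes")
        lib_sizes[idx] = max(lib_sizes[idx], 60000)

    # per-cell activity = cluster activity + jitter
    cell_act = activities[:, labels - 1].T  # cells x regulators
    if activity_sd > 0:
        cell_act = cell_act + rng.normal(0.0, activity_sd, size=cell_act.shape)

    shape = 1.0 / nb_dispersion
    cols = []
    for c in range(n_cells):
        log2_mu = base + coef @ cell_act[c]
        w = np.power(2.0, log2_mu)
        w *= rng.gamma(shape, scale=1.0 / shape, size=n_genes)  # NB overdispersion
        # impose the requested mitochondrial share in expectation
        f = mito_frac[c]
        w_m, w_r = w[mito].sum(), w[N_MITO_GENES:].sum()
        w[mito] *= f / w_m * (w_m + w_r)
        w[N_MITO_GENES:] *= (1.0 - f) / w_r * (w_m + w_r)
        if c in restricted:
            allowed = np.zeros(n_genes, dtype=bool)
            order = np.argsort(w)[::-1]
            allowed[order[: restricted[c]]] = True
            w = np.where(allowed, w, 0.0)
        p = w / w.sum()
        cols.append(rng.multinomial(lib_sizes[c], p))
    counts = sp.csr_matrix(np.column_stack(cols))

    width = len(str(n_cells))
    barcodes = np.array([f"cell{i + 1:0{width}d}" for i in range(n_cells)], dtype=object)
    sample_ids = np.array([f"S{(i % n_samples) + 1}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {
            "sample": sample_ids,
            "group": np.where(
                pd.Series(sample_ids).str[1:].astype(int) <= max(1, n_samples // 2),
                "healthy",
                "disease",
            ),
            "true_cluster": labels,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    gem = GeneExpressionMatrix(counts, np.array(gene_ids, dtype=object), barcodes, meta)
    bundle = TruthBundle(
        network=truth,
        cluster_activities=activities,
        cell_labels=labels,
        bulk_effects={},
        seed=seed,
        cell_activities=cell_act,
    )
    return gem, bundle


def simulate_bulk_counts(
    truth: TruthNetwork,
    n_group1: int = 18,
    n_group2: int = 20,
    bulk_effects: dict[str, float] | None = None,
    dispersion: float = 0.1,
    lib_size: float = 2e6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group bulk cohort; group 2 ("disease") carries the activity shifts.

    Mirrors an 18-healthy vs 20-disease cartilage cohort by default.  Returns
    (counts genes x samples, planted per-gene log2 fold change).
    """
    if n_group1 < 2 or n_group2 < 2:
        raise ValueError("each group needs at least 2 samples")
    bulk_effects = dict(bulk_effects or {})
    if not bulk_effects:
        warnings.warn("empty bulk_effects: generating a null-signal cohort")
    unknown = set(bulk_effects) - set(truth.regulators)
    if unknown:
        raise ValueError(f"bulk_effects names unknown regulators: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    gene_ids = truth.gene_ids
    gidx = {g: i for i, g in enumerate(gene_ids)}
    base = _base_log2_abundance(truth.n_genes, rng)
    shift = _gene_log2_shift(truth, bulk_effects, gidx)

    n = n_group1 + n_group2
    groups = np.array(["healthy"] * n_group1 + ["disease"] * n_group2)
    libs = rng.lognormal(np.log(lib_size), 0.15, size=n)
    shape = 1.0 / dispersion
    cols = np.empty((truth.n_genes, n))
    for j in range(n):
        log2_mu = base + (shift if groups[j] == "disease" else 0.0)
        w = np.power(2.0, log2_mu)
        w *= rng.gamma(shape, scale=1.0 / shape, size=truth.n_genes)
        lam = w / w.sum() * libs[j]
        cols[:, j] = rng.poisson(lam)
    samples = [f"H{i + 1}" for i in range(n_group1)] + [f"OA{i + 1}" for i in range(n_group2)]
    counts = pd.DataFrame(cols.astype(int), index=gene_ids, columns=samples)
    truth_de = pd.Series(shift, index=gene_ids, name="log2fc")
    return counts, truth_de


# ---------------------------------------------------------------------------
# on-disk export (MTX + TSV triplet layout, truth bundle as JSON)

def write_sc_dataset(gem: GeneExpressionMatrix, bundle: TruthBundle, outdir: str | Path) -> None:
    from . import io as scpa_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scpa_io.write_counts(gem, outdir / "matrix.mtx", outdir / "genes.tsv", outdir / "barcodes.tsv")
    gem.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "regulators": bundle.network.regulators,
                "edges": bundle.network.edges,
                "regulon_size": bundle.network.regulon_size,
                "n_genes": bundle.network.n_genes,
                "gene_ids": bundle.network.gene_ids,
                "cluster_activities": bundle.cluster_activities.tolist(),
                "cell_labels": bundle.cell_labels.tolist(),
                "bulk_effects": bundle.bulk_effects,
                "seed": bundle.seed,
                "cell_activities": (
                    bundle.cell_activities.tolist()
                    if bundle.cell_activities is not None else None
                ),
            },
            fh,
        )


def read_truth_bundle(path: str | Path) -> TruthBundle:
    with open(path) as fh:
        d = json.load(fh)
    net = TruthNetwork(
        regulators=d["regulators"],
        edges=[tuple(e) for e in d["edges"]],
        regulon_size=d["regulon_size"],
        n_genes=d["n_genes"],
        gene_ids=d["gene_ids"],
    )
    return TruthBundle(
        network=net,
        cluster_activities=np.asarray(d["cluster_activities"], dtype=float),
        cell_labels=np.asarray(d["cell_labels"], dtype=int),
        bulk_effects=d["bulk_effects"],
        seed=d["seed"],
        cell_activities=(
            np.asarray(d["cell_activities"], dtype=float)
            if d.get("cell_activities") is not None else None
        ),
    )
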