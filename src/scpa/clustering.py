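"""Dimensionality reduction, resolution-optimized Louvain clustering,
marker detection and over-representation analysis.

The clustering recipe: PCA on highly-variable-gene residuals, a shared
nearest-neighbor (SNN) graph with Jaccard edge weights from Euclidean KNN in
PC space, Louvain modularity optimization, and resolution selection by the
mean silhouette score (correlation distance) over repeated random cell
subsamples on a grid of resolutions in [0.01, 1.0].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .qc import NormalizedMatrix

DEFAULT_RESOLUTION_GRID = np.round(np.linspace(0.01, 1.0, 25), 4)


@dataclass
class Embedding:
    coords: np.ndarray              # cells x n_pcs
    explained_variance: np.ndarray  # per PC, decreasing
    n_pcs: int
    cell_ids: np.ndarray


@dataclass
class ClusterAssignment:
    labels: np.ndarray              # 1-based contiguous, by decreasing size
    resolution: float
    mean_silhouette: float
    silhouette_trace: pd.DataFrame  # columns: resolution, mean, sd
    cell_ids: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def run_pca(norm: NormalizedMatrix, n_pcs: int = 30) -> Embedding:
    """PCA of cells over HVG residuals; gene rows are centered.

    Column signs are fixed by making each component's largest-magnitude
    loading positive, so repeated runs give identical coordinates.
    """
    if n_pcs <= 0:
        raise ValueError("n_pcs must be positive")
    view = norm.hvg_view() if norm.hvg_flags.any() else norm
    x = view.values.T.astype(float)  # cells x genes
    x = x - x.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(x)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return Embedding(coords, pca.explained_variance_.copy(), n_pcs, norm.cell_ids.copy())


def elbow_n_pcs(explained_variance: np.ndarray) -> int:
    """Advisory elbow: PC with maximum distance to the chord of the scree curve."""
    ev = np.asarray(explained_variance, dtype=float)
    n = len(ev)
    if n < 3:
        return n
    x = np.arange(n, dtype=float)
    p0, p1 = np.array([0.0, ev[0]]), np.array([n - 1.0, ev[-1]])
    d = p1 - p0
    d /= np.linalg.norm(d)
    dist = np.abs(d[0] * (ev - p0[1]) - d[1] * (x - p0[0]))
    return int(np.argmax(dist)) + 1


def snn_graph(coords: np.ndarray, k_neighbors: int = 20) -> nx.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of Euclidean KNN lists."""
    n = coords.shape[0]
    if n < k_neighbors + 1:
        raise ValueError("need more cells than k_neighbors")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_sets = [set(row) for row in idx]  # includes self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w > 0:
                g.add_edge(i, j, weight=w)
    return g


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """1-based contiguous labels ordered by decreasing cluster size."""
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[v] for v in raw])


def _louvain_labels(g: nx.Graph, resolution: float, seed: int) -> np.ndarray:
    comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=int(seed))
    raw = np.empty(g.number_of_nodes(), dtype=int)
    for cid, members in enumerate(comms):
        for node in members:
            raw[node] = cid
    return _relabel_by_size(raw)


def louvain_cluster(
    embedding: Embedding, k_neighbors: int = 20, resolution: float = 0.5, seed: int = 0
) -> ClusterAssignment:
    """Louvain clustering of the SNN graph at a fixed resolution."""
    g = snn_graph(embedding.coords, k_neighbors)
    labels = _louvain_labels(g, resolution, seed)
    trace = pd.DataFrame(columns=["resolution", "mean", "sd"])
    try:
        sil = silhouette_correlation(embedding.coords, labels)
    except ValueError:
        sil = float("nan")
    return ClusterAssignment(labels, resolution, sil, trace, embedding.cell_ids.copy())


def _correlation_distances(coords: np.ndarray) -> np.ndarray:
    d = 1.0 - np.corrcoef(coords)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def silhouette_correlation(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width with d(x, y) = 1 - Pearson r(x, y) over PC coords."""
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(_correlation_distances(coords), labels, metric="precomputed"))


def optimize_resolution(
    embedding: Embedding,
    grid: np.ndarray | None = None,
    n_repeats: int = 100,
    subsample: int = 500,
    k_neighbors: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """Pick the Louvain resolution maximizing mean silhouette over subsamples.

    For each of ``n_repeats`` random subsamples (size ``min(subsample,
    n_cells)``) the SNN graph and correlation-distance matrix are built once
    and every grid resolution is scored on them; the resolution with the
    highest mean silhouette wins (ties -> smaller resolution) and the final
    clustering is run on all cells at that resolution.
    """
    grid = DEFAULT_RESOLUTION_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.min() < 0.01 - 1e-12 or grid.max() > 1.0 + 1e-12:
        raise ValueError("resolution grid must lie within [0.01, 1.0]")
    n = embedding.coords.shape[0]
    size = min(subsample, n)
    if size < 50:
        warnings.warn("subsample < 50 cells: silhouette estimates will be unstable")
    rng = np.random.default_rng(seed)
    scores = np.zeros((len(grid), n_repeats))
    for rep in range(n_repeats):
        idx = rng.choice(n, size=size, replace=False) if size < n else np.arange(n)
        sub = embedding.coords[idx]
        g = snn_graph(sub, min(k_neighbors, size - 1))
        dist = _correlation_distances(sub)
        for gi, res in enumerate(grid):
            labels = _louvain_labels(g, float(res), seed=int(rng.integers(2**31 - 1)))
            if len(np.unique(labels)) < 2:
                scores[gi, rep] = 0.0  # single cluster: no separation evidence
            else:
                scores[gi, rep] = silhouette_score(dist, labels, metric="precomputed")
    means = scores.mean(axis=1)
    sds = scores.std(axis=1)
    best = int(np.argmax(means))  # argmax returns the first (smallest) resolution on ties
    trace = pd.DataFrame({"resolution": grid, "mean": means, "sd": sds})
    final = louvain_cluster(embedding, k_neighbors, float(grid[best]), seed=seed)
    final.silhouette_trace = trace
    return final


def find_markers(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    depth_norm_counts: np.ndarray | None = None,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster with Bonferroni control.

    The test runs on the normalized residuals; log2 fold changes are taken on
    depth-normalized counts when provided (CPM-style), otherwise on shifted
    residual means.  p_adj = min(1, p * n_genes * n_clusters).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    values = norm.values
    fc_source = depth_norm_counts if depth_norm_counts is not None else None
    rows = []
    n_tests = 0
    for c in clusters:
        in_mask = labels == c
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {c} has fewer than 2 cells; skipped")
            continue
        x_in, x_out = values[:, in_mask], values[:, ~in_mask]
        res = stats.mannwhitneyu(x_in, x_out, axis=1, alternative="two-sided",
                                 method="asymptotic")
        pvals = np.atleast_1d(res.pvalue)
        if fc_source is not None:
            m_in = fc_source[:, in_mask].mean(axis=1)
            m_out = fc_source[:, ~in_mask].mean(axis=1)
        else:
            shift = values.min() if values.size else 0.0
            m_in = x_in.mean(axis=1) - shift
            m_out = x_out.mean(axis=1) - shift
        logfc = np.log2(m_in + eps) - np.log2(m_out + eps)
        pct_in = (x_in != 0).mean(axis=1) * 100
        pct_out = (x_out != 0).mean(axis=1) * 100
        n_tests += len(norm.gene_ids)
        for gi, gene in enumerate(norm.gene_ids):
            rows.append((int(c), gene, logfc[gi], pvals[gi], pct_in[gi], pct_out[gi]))
    table = pd.DataFrame(rows, columns=["cluster", "gene", "logFC", "p", "pct_in", "pct_out"])
    table["p_adj_bonferroni"] = np.minimum(1.0, table["p"] * n_tests)
    return table[["cluster", "gene", "logFC", "p", "p_adj_bonferroni", "pct_in", "pct_out"]]


def top_markers(table: pd.DataFrame, n: int = 50) -> dict[int, list[str]]:
    """Top-n markers per cluster by (p, -logFC); default 50 per cluster."""
    out: dict[int, list[str]] = {}
    for c, sub in table.groupby("cluster"):
        ordered = sub.sort_values(["p", "logFC", "gene"], ascending=[True, False, True])
        out[int(c)] = ordered["gene"].head(n).tolist()
    return out


def ora_enrichment(
    gene_list: list[str], gene_sets: dict[str, set[str]], universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each gene set.

    p is the upper-tail hypergeometric probability of the observed overlap;
    Bonferroni is applied across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(gene_list) & uni
    if set(gene_list) - uni:
        raise ValueError("gene_list must be a subset of the universe")
    big_n, n_query = len(uni), len(query)
    rows = []
    for name, members in gene_sets.items():
        hits = members & uni
        overlap = len(hits & query)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, len(hits), n_query))
        rows.append((name, overlap, len(hits), p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_hypergeometric"])
    table["p_adj_bonferroni"] = np.minimum(1.0, table["p_hypergeometric"] * len(gene_sets))
    return table.sort_values("p_hypergeometric", kind="stable").reset_index(drop=True)
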