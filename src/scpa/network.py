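"""KNN metaCell pooling and mutual-information regulon inference.

Network inference follows the ARACNe recipe: pairwise mutual information
between regulator and target expression estimated by adaptive partitioning
of the rank plane, an MI significance threshold calibrated on a permutation
null with an exponential tail fit, data-processing-inequality (DPI) pruning
of the weakest edge in every MI triangle, and a bootstrap consensus that
keeps edges whose support across resamples beats a Bonferroni-corrected
Poisson upper tail.

metaCells mitigate single-cell dropout before inference: per expression
cluster, up to 250 seed cells are drawn and each is pooled with its k nearest
same-cluster neighbors in PC space by summing raw UMI counts, then
re-normalized to log2(CPM+1).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .clustering import Embedding
from .containers import GeneExpressionMatrix

CHI2_CRIT_5PCT_DF3 = 7.814727903251179  # quadrant-occupancy split test


@dataclass
class MetaCellMatrix:
    values: np.ndarray            # genes x metacells, log2(CPM+1)
    raw: np.ndarray               # genes x metacells, pooled UMI counts
    gene_ids: np.ndarray
    origin_cluster: np.ndarray    # per metacell
    members: list[list[int]]      # per metacell: pooled cell positions
    k: int

    @property
    def n_metacells(self) -> int:
        return self.values.shape[1]


@dataclass
class Regulon:
    regulator: str
    targets: list[str]
    tfmode: np.ndarray            # per target, in [-1, 1]
    likelihood: np.ndarray        # per target, in (0, 1], max == 1

    def __post_init__(self) -> None:
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate targets in regulon")
        if self.regulator in self.targets:
            raise ValueError("regulator cannot be its own target")

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class InteractionNetwork:
    context_id: str
    regulons: list[Regulon]
    mi_threshold: float
    n_bootstraps: int
    edge_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def regulators(self) -> list[str]:
        return [r.regulator for r in self.regulons]


# ---------------------------------------------------------------------------
# metaCell pooling

def pool_metacells(
    counts: GeneExpressionMatrix,
    labels: np.ndarray,
    embedding: Embedding,
    n_meta: int = 250,
    k: int = 10,
    seed: int = 0,
) -> MetaCellMatrix:
    """Pool raw counts over k nearest same-cluster neighbors (seed included).

    Per cluster, min(n_meta, cluster size) seed cells are sampled without
    replacement; k=1 reduces to pass-through of single cells.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    dense = counts.to_dense()
    cols, raws, origins, members = [], [], [], []
    for c in np.unique(labels):
        pos = np.flatnonzero(labels == c)
        if len(pos) < 2:
            warnings.warn(f"cluster {c} has <2 cells; passing cells through as metacells")
            for p in pos:
                raws.append(dense[:, p].copy())
                origins.append(c)
                members.append([int(p)])
            continue
        kc = min(k, len(pos))
        seeds = rng.choice(pos, size=min(n_meta, len(pos)), replace=False)
        nn = NearestNeighbors(n_neighbors=kc).fit(embedding.coords[pos])
        _, idx = nn.kneighbors(embedding.coords[seeds])
        for row in idx:
            pooled_cells = pos[row]
            raws.append(dense[:, pooled_cells].sum(axis=1))
            origins.append(c)
            members.append([int(p) for p in pooled_cells])
    raw = np.column_stack(raws)
    lib = raw.sum(axis=0)
    cpm = raw / np.maximum(lib, 1) * 1e6
    values = np.log2(cpm + 1.0)
    return MetaCellMatrix(values, raw, counts.gene_ids.copy(),
                          np.asarray(origins), members, k)


# ---------------------------------------------------------------------------
# mutual information

@njit(cache=True)
def _mi_adaptive_ranks(px: np.ndarray, py: np.ndarray) -> float:
    """Adaptive-partition MI (nats) on integer rank pairs.

    Recursive quadrant splitting of the rank plane; a split is accepted when
    the chi-square of quadrant occupancy exceeds the 5% critical value
    (df=3).  Leaves contribute n/N * log(n*N / (n_row*n_col)).
    """
    n = px.shape[0]
    wx = px.copy().astype(np.float64)
    wy = py.copy().astype(np.float64)
    # stack: start, end, x1, x2, y1, y2 (region is [x1,x2) x [y1,y2))
    max_depth = 4 * n + 64
    st_s = np.empty(max_depth, dtype=np.int64)
    st_e = np.empty(max_depth, dtype=np.int64)
    st_x1 = np.empty(max_depth); st_x2 = np.empty(max_depth)
    st_y1 = np.empty(max_depth); st_y2 = np.empty(max_depth)
    top = 0
    st_s[0] = 0; st_e[0] = n
    st_x1[0] = 0.0; st_x2[0] = float(n)
    st_y1[0] = 0.0; st_y2[0] = float(n)
    top = 1
    mi = 0.0
    nf = float(n)
    while top > 0:
        top -= 1
        s, e = st_s[top], st_e[top]
        x1, x2 = st_x1[top], st_x2[top]
        y1, y2 = st_y1[top], st_y2[top]
        m = e - s
        if m == 0:
            continue
        xm = 0.5 * (x1 + x2)
        ym = 0.5 * (y1 + y2)
        # the root split is unconditional (ARACNe convention); below it a
        # split must pass the chi-square occupancy test
        split = (s == 0) and (e == n) and (x2 - x1) >= nf and m >= 4
        if not split and m >= 3 and (x2 - x1) > 2.0 and (y2 - y1) > 2.0:
            c1 = 0; c2 = 0; c3 = 0; c4 = 0
            for i in range(s, e):
                if wx[i] < xm:
                    if wy[i] < ym:
                        c1 += 1
                    else:
                        c2 += 1
                else:
                    if wy[i] < ym:
                        c3 += 1
                    else:
                        c4 += 1
            expct = m / 4.0
            tst = ((c1 - expct) ** 2 + (c2 - expct) ** 2
                   + (c3 - expct) ** 2 + (c4 - expct) ** 2) / expct
            split = tst > CHI2_CRIT_5PCT_DF3
        if split:
            # partition points into quadrants: [s,a)=q1, [a,b)=q2, [b,c)=q3, [c,e)=q4
            a = s
            for i in range(s, e):
                if wx[i] < xm and wy[i] < ym:
                    wx[i], wx[a] = wx[a], wx[i]
                    wy[i], wy[a] = wy[a], wy[i]
                    a += 1
            b = a
            for i in range(a, e):
                if wx[i] < xm and wy[i] >= ym:
                    wx[i], wx[b] = wx[b], wx[i]
                    wy[i], wy[b] = wy[b], wy[i]
                    b += 1
            c = b
            for i in range(b, e):
                if wx[i] >= xm and wy[i] < ym:
                    wx[i], wx[c] = wx[c], wx[i]
                    wy[i], wy[c] = wy[c], wy[i]
                    c += 1
            st_s[top] = s; st_e[top] = a
            st_x1[top] = x1; st_x2[top] = xm; st_y1[top] = y1; st_y2[top] = ym
            top += 1
            st_s[top] = a; st_e[top] = b
            st_x1[top] = x1; st_x2[top] = xm; st_y1[top] = ym; st_y2[top] = y2
            top += 1
            st_s[top] = b; st_e[top] = c
            st_x1[top] = xm; st_x2[top] = x2; st_y1[top] = y1; st_y2[top] = ym
            top += 1
            st_s[top] = c; st_e[top] = e
            st_x1[top] = xm; st_x2[top] = x2; st_y1[top] = ym; st_y2[top] = y2
            top += 1
        else:
            p = m / nf
            prow = (x2 - x1) / nf
            pcol = (y2 - y1) / nf
            mi += p * np.log(p / (prow * pcol))
    if mi < 0.0:
        mi = 0.0
    return mi


@njit(cache=True)
def _mi_pairs(ranks: np.ndarray, reg_idx: np.ndarray, tgt_idx: np.ndarray) -> np.ndarray:
    """Adaptive-partition MI for each (reg_idx[i], tgt_idx[i]) rank-row pair."""
    out = np.empty(reg_idx.shape[0])
    for i in range(reg_idx.shape[0]):
        out[i] = _mi_adaptive_ranks(ranks[reg_idx[i]], ranks[tgt_idx[i]])
    return out


def _deterministic_ranks(values: np.ndarray, seed: int) -> np.ndarray:
    """Row-wise 0-based ranks with deterministic seeded tie-jitter."""
    rng = np.random.default_rng(seed)
    sd = values.std(axis=1, keepdims=True)
    jitter = rng.normal(0.0, 1.0, size=values.shape) * (1e-9 * np.maximum(sd, 1e-12))
    order = np.argsort(values + jitter, axis=1, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(values.shape[1])
    for i in range(values.shape[0]):
        ranks[i, order[i]] = cols
    return ranks.astype(np.int64)


def estimate_mi(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "adaptive_partition",
    bins: int | None = None,
    seed: int = 0,
) -> float:
    """Mutual information (nats) between two samples of equal length.

    ``adaptive_partition`` is the production estimator; ``equal_freq_bins``
    is the simple binned variant kept as an independent oracle.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 8:
        raise ValueError("need at least 8 observations")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant vector: MI = 0")
        return 0.0
    ranks = _deterministic_ranks(np.vstack([x, y]), seed)
    if method == "adaptive_partition":
        return float(_mi_adaptive_ranks(ranks[0], ranks[1]))
    if method == "equal_freq_bins":
        n = len(x)
        b = bins if bins is not None else max(2, int(round(np.sqrt(n / 5.0))))
        bx = (ranks[0] * b) // n
        by = (ranks[1] * b) // n
        joint = np.zeros((b, b))
        for i, j in zip(bx, by):
            joint[i, j] += 1
        joint /= n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * np.log(joint / (px * py))
        return float(np.nansum(terms))
    raise ValueError(f"unknown MI method {method!r}")


def mi_null_threshold(
    metacells: MetaCellMatrix,
    regulators: list[str] | None = None,
    n_null_pairs: int = 1000,
    p_threshold: float = 1e-8,
    seed: int = 0,
    tail_fraction: float = 0.2,
) -> float:
    """MI significance threshold from a permutation null.

    Random expression pairs are decoupled by permuting one member; within the
    empirical range the threshold is the (1 - p) quantile, and deeper tails
    are extrapolated by an exponential fit (linear regression of log p on MI
    over the upper ``tail_fraction`` of the null).
    """
    if n_null_pairs < 100:
        raise ValueError("need at least 100 null pairs for a tail fit")
    rng = np.random.default_rng(seed)
    values = metacells.values
    n_genes, n_obs = values.shape
    expressed = np.flatnonzero(values.std(axis=1) > 0)
    if len(expressed) < 2:
        raise ValueError("not enough variable genes for a null")
    null = np.empty(n_null_pairs)
    ranks = _deterministic_ranks(values, seed=seed + 1)
    for i in range(n_null_pairs):
        gi, gj = rng.choice(expressed, size=2, replace=False)
        perm = rng.permutation(n_obs)
        null[i] = _mi_adaptive_ranks(ranks[gi], ranks[gj][perm])
    null.sort()
    if p_threshold >= 1.0 / n_null_pairs:
        return float(np.quantile(null, 1.0 - p_threshold))
    k = max(10, int(np.ceil(tail_fraction * n_null_pairs)))
    tail = null[-k:]
    emp_p = (n_null_pairs - (n_null_pairs - k + np.arange(k))) / n_null_pairs
    # emp_p runs k/N .. 1/N over ascending tail MIs
    slope, intercept = np.polyfit(tail, np.log(emp_p), 1)
    if slope >= 0:
        raise ValueError("null tail is not decaying; cannot extrapolate threshold")
    # the deep-tail extrapolation can never fall below the largest observed
    # null value, keeping the threshold monotone across the two regimes
    return float(max((np.log(p_threshold) - intercept) / slope, null[-1]))


# ---------------------------------------------------------------------------
# DPI

def apply_dpi(
    edges: list[tuple], tolerance: float = 0.0
) -> list[tuple]:
    """Data-processing-inequality pruning.

    For every triangle the weakest edge (a,c) is removed when
    MI(a,c) < min(MI(a,b), MI(b,c)) * (1 - tolerance); all removals are
    evaluated against the original edge set (simultaneous semantics).
    """
    adj: dict = {}
    for a, b, mi in edges:
        key = (a, b) if a <= b else (b, a)
        if b in adj.get(a, {}):
            raise ValueError(f"duplicate edge for pair {key}")
        adj.setdefault(a, {})[b] = mi
        adj.setdefault(b, {})[a] = mi
    removed = set()
    for a, b, mi in edges:
        small, large = (a, b) if len(adj[a]) <= len(adj[b]) else (b, a)
        for c in adj[small]:
            if c == large or c not in adj[large]:
                continue
            if mi < min(adj[a][c], adj[b][c]) * (1.0 - tolerance):
                removed.add((a, b) if a <= b else (b, a))
                break
    return [e for e in edges if ((e[0], e[1]) if e[0] <= e[1] else (e[1], e[0])) not in removed]


# ---------------------------------------------------------------------------
# bootstrap consensus

def _candidate_pairs(gene_ids: np.ndarray, regulators: list[str]) -> tuple[np.ndarray, np.ndarray]:
    gidx = {g: i for i, g in enumerate(gene_ids)}
    reg_pos = [gidx[r] for r in regulators if r in gidx]
    reg_set = set(reg_pos)
    ri, ti = [], []
    for rp in reg_pos:
        for tp in range(len(gene_ids)):
            if tp == rp:
                continue
            if tp in reg_set and tp < rp:
                continue  # unordered regulator-regulator pair counted once
            ri.append(rp)
            ti.append(tp)
    return np.asarray(ri, dtype=np.int64), np.asarray(ti, dtype=np.int64)


def bootstrap_consensus_network(
    metacells: MetaCellMatrix,
    regulators: list[str] | dict[str, list[str]],
    n_boot: int = 100,
    p_threshold: float = 1e-8,
    dpi_tolerance: float = 0.0,
    seed: int = 0,
    n_null_pairs: int = 1000,
    context_id: str = "all",
    consensus_alpha: float = 0.05,
    bootstrap_noise_sd: float = 0.1,
) -> InteractionNetwork:
    """ARACNe-style network: bootstrap, threshold, DPI, Poisson consensus.

    ``regulators`` may be a flat list or a dict of regulator classes; classes
    are run separately and their edge sets unioned.  Edges are kept when
    their occurrence count across bootstraps exceeds the Bonferroni-corrected
    upper tail of a Poisson with the mean per-edge count.

    Each bootstrap adds Gaussian noise (``bootstrap_noise_sd`` x per-gene SD)
    before ranking: resampling with replacement duplicates observations, and
    identical point pairs would otherwise register as spurious fine-scale
    dependence under any rank-based MI estimator.
    """
    if metacells.n_metacells < 10:
        raise ValueError("fewer than 10 metacells: network would be unstable")
    classes = regulators if isinstance(regulators, dict) else {"all": list(regulators)}
    gene_ids = metacells.gene_ids
    gidx = {g: i for i, g in enumerate(gene_ids)}
    expressed = metacells.values.std(axis=1) > 0

    threshold = mi_null_threshold(
        metacells, n_null_pairs=n_null_pairs, p_threshold=p_threshold, seed=seed
    )

    rng = np.random.default_rng(seed)
    counts: dict[tuple[int, int], int] = {}
    mi_sums: dict[tuple[int, int], float] = {}
    candidates: set[tuple[int, int]] = set()
    n_obs = metacells.n_metacells
    for class_name, reg_list in classes.items():
        present = [r for r in reg_list if r in gidx and expressed[gidx[r]]]
        missing = set(reg_list) - set(present)
        if missing:
            warnings.warn(
                f"class {class_name!r}: {len(missing)} regulators absent/constant; skipped"
            )
        if not present:
            continue
        ri, ti = _candidate_pairs(gene_ids, present)
        usable = expressed[ti]
        ri, ti = ri[usable], ti[usable]
        candidates.update(
            (int(a), int(b_)) if a <= b_ else (int(b_), int(a)) for a, b_ in zip(ri, ti)
        )
        row_sd = metacells.values.std(axis=1, keepdims=True)
        for b in range(n_boot):
            cols = rng.integers(0, n_obs, size=n_obs)
            vals = metacells.values[:, cols]
            if bootstrap_noise_sd > 0:
                vals = vals + rng.normal(0.0, 1.0, size=vals.shape) * (bootstrap_noise_sd * row_sd)
            ranks = _deterministic_ranks(vals, seed=int(rng.integers(2**31 - 1)))
            mi = _mi_pairs(ranks, ri, ti)
            keep = mi >= threshold
            edges = [(int(a), int(b_), float(m)) for a, b_, m in zip(ri[keep], ti[keep], mi[keep])]
            for a, b_, m in apply_dpi(edges, dpi_tolerance):
                key = (a, b_) if a <= b_ else (b_, a)
                counts[key] = counts.get(key, 0) + 1
                mi_sums[key] = mi_sums.get(key, 0.0) + m

    if not counts:
        return InteractionNetwork(context_id, [], threshold, n_boot,
                                  pd.DataFrame(columns=["a", "b", "count", "mi"]))
    n_tested = max(len(candidates), 1)
    mu = sum(counts.values()) / n_tested  # mean per-edge count over all tested pairs
    crit = stats.poisson.isf(consensus_alpha / n_tested, mu)
    rows = [
        (gene_ids[a], gene_ids[b], c, mi_sums[(a, b)] / c)
        for (a, b), c in counts.items()
        if c > crit
    ]
    table = pd.DataFrame(rows, columns=["a", "b", "count", "mi"])
    net = InteractionNetwork(context_id, [], threshold, n_boot, table)
    return net


def build_regulons(
    network: InteractionNetwork,
    metacells: MetaCellMatrix,
    max_targets: int = 50,
    min_targets: int = 25,
    regulators: list[str] | None = None,
) -> list[Regulon]:
    """Attach mode-of-regulation and likelihood weights to consensus edges.

    tfmode = Spearman correlation of regulator and target across metacells;
    likelihood = edge MI / max edge MI within the regulon.  Regulons are
    truncated to ``max_targets`` by likelihood and dropped below
    ``min_targets``.
    """
    table = network.edge_table
    if table.empty:
        raise ValueError("network has no edges")
    gidx = {g: i for i, g in enumerate(metacells.gene_ids)}
    reg_set = set(regulators) if regulators is not None else None

    by_reg: dict[str, list[tuple[str, float]]] = {}
    for _, row in table.iterrows():
        a, b, mi = row["a"], row["b"], row["mi"]
        for reg, tgt in ((a, b), (b, a)):
            if reg_set is not None and reg not in reg_set:
                continue
            by_reg.setdefault(reg, []).append((tgt, float(mi)))

    regulons = []
    for reg, pairs in sorted(by_reg.items()):
        if reg not in gidx:
            warnings.warn(f"regulator {reg!r} absent from expression matrix; dropped")
            continue
        pairs = sorted(pairs, key=lambda p: (-p[1], p[0]))[:max_targets]
        if len(pairs) < min_targets:
            continue
        targets = [t for t, _ in pairs]
        mis = np.array([m for _, m in pairs])
        x = metacells.values[gidx[reg]]
        tfmode = np.array([
            stats.spearmanr(x, metacells.values[gidx[t]]).statistic for t in targets
        ])
        tfmode = np.nan_to_num(tfmode, nan=0.0)
        likelihood = mis / mis.max()
        regulons.append(Regulon(reg, targets, tfmode, likelihood))
    network.regulons = regulons
    return regulons


def write_regulons(regulons: list[Regulon], path) -> None:
    rows = []
    for r in regulons:
        for t, m, lik in zip(r.targets, r.tfmode, r.likelihood):
            rows.append((r.regulator, t, m, lik))
    pd.DataFrame(rows, columns=["regulator", "target", "tfmode", "likelihood"]).to_csv(
        path, sep="\t", index=False
    )


def read_regulons(path) -> list[Regulon]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for reg, sub in df.groupby("regulator", sort=True):
        out.append(Regulon(
            str(reg), sub["target"].tolist(),
            sub["tfmode"].to_numpy(float), sub["likelihood"].to_numpy(float),
        ))
    return out
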