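"""Protein-activity inference: signatures, aREA, metaVIPER, master regulators.

The analytic rank-based enrichment analysis (aREA) scores a regulon against a
per-cell gene-expression signature.  Genes are rank-transformed to quantiles
of the standard normal; each target contributes a directional component
weighted by its mode of regulation (tfmode) and a magnitude component for the
unsigned remainder; the likelihood-weighted sum is normalized so the null is
approximately N(0, 1), giving a normalized enrichment score (NES).

metaVIPER integrates NES across multiple context-specific networks with
confidence weights proportional to NES^2, so the network that resolves a
protein most strongly dominates, and a protein carried by a single network
passes through unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import InteractionNetwork, Regulon
from .qc import NormalizedMatrix


@dataclass
class SignatureMatrix:
    """Per-gene z-scores of normalized expression against the all-cell mean/SD."""

    values: np.ndarray   # genes x cells
    gene_ids: np.ndarray
    cell_ids: np.ndarray


@dataclass
class ActivityMatrix:
    values: np.ndarray   # proteins x cells (NES)
    protein_ids: np.ndarray
    cell_ids: np.ndarray
    provenance: dict[str, list[str]] = field(default_factory=dict)


def compute_signatures(
    values: np.ndarray,
    gene_ids: np.ndarray,
    cell_ids: np.ndarray,
    method: str = "zscore",
) -> SignatureMatrix:
    """Per-gene signature against the internal all-cell reference.

    ``zscore``: (x - mean)/SD per gene across cells; ``rank-normal``: cells
    rank-transformed per gene then mapped through the normal quantile.
    Constant genes get 0.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 cells for an internal reference")
    if method == "zscore":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sig = np.where(sd > 0, (values - mean) / np.maximum(sd, 1e-300), 0.0)
    elif method == "rank-normal":
        n = values.shape[1]
        ranks = stats.rankdata(values, axis=1)
        sig = stats.norm.ppf(ranks / (n + 1))
        sig[values.std(axis=1) == 0, :] = 0.0
    else:
        raise ValueError(f"unknown signature method {method!r}")
    return SignatureMatrix(sig, np.asarray(gene_ids, dtype=object),
                           np.asarray(cell_ids, dtype=object))


def default_min_targets(n_genes_universe: int) -> int:
    """aREA regulon-size floor: 25, relaxed to 10 for small gene universes."""
    return 10 if n_genes_universe < 2000 else 25


def _rank_quantiles(signature_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directional (q1) and magnitude (q2) normal quantiles of per-cell ranks."""
    n = signature_values.shape[0]
    ranks = stats.rankdata(signature_values, axis=0)
    r = ranks / (n + 1)
    q1 = stats.norm.ppf(r)
    q2 = stats.norm.ppf(0.5 + np.abs(r - 0.5))
    return q1, q2


def area_nes(
    signatures: SignatureMatrix,
    regulon: Regulon,
    min_targets: int | None = None,
    _quantiles: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """aREA NES of one regulon for every cell; ~N(0,1) under the null."""
    min_targets = min_targets if min_targets is not None else default_min_targets(len(signatures.gene_ids))
    gidx = {g: i for i, g in enumerate(signatures.gene_ids)}
    usable = [(gidx[t], m, l) for t, m, l in
              zip(regulon.targets, regulon.tfmode, regulon.likelihood) if t in gidx]
    if len(usable) < min_targets:
        raise ValueError(
            f"regulon {regulon.regulator!r}: {len(usable)} usable targets < {min_targets}"
        )
    idx = np.array([u[0] for u in usable])
    mode = np.array([u[1] for u in usable])
    lik = np.array([u[2] for u in usable])
    q1, q2 = _quantiles if _quantiles is not None else _rank_quantiles(signatures.values)
    s = mode[:, None] * q1[idx] + (1.0 - np.abs(mode))[:, None] * q2[idx]
    w = lik / lik.sum()
    es = w @ s
    return es / np.sqrt(np.sum(w ** 2))


def viper_activity(
    signatures: SignatureMatrix,
    network: InteractionNetwork,
    min_targets: int | None = None,
) -> ActivityMatrix:
    """Single-network VIPER: aREA NES for every regulon in the network."""
    q = _rank_quantiles(signatures.values)
    rows, ids = [], []
    for reg in network.regulons:
        try:
            rows.append(area_nes(signatures, reg, min_targets, _quantiles=q))
        except ValueError:
            continue
        ids.append(reg.regulator)
    if not rows:
        raise ValueError("no regulon met the aREA size floor")
    return ActivityMatrix(
        np.vstack(rows), np.asarray(ids, dtype=object), signatures.cell_ids.copy(),
        {r: [network.context_id] for r in ids},
    )


def metaviper_activity(
    signatures: SignatureMatrix,
    networks: list[InteractionNetwork],
    min_targets: int | None = None,
) -> ActivityMatrix:
    """Integrate per-network NES with confidence weights w_n = NES_n^2.

    Integrated NES = sum_n w_n NES_n / sqrt(sum_n w_n^2); a protein carried by
    exactly one network passes through unchanged.  Order-invariant.
    """
    if not networks:
        raise ValueError("need at least one network")
    q = _rank_quantiles(signatures.values)
    per_protein: dict[str, list[tuple[str, np.ndarray]]] = {}
    for net in networks:
        for reg in net.regulons:
            try:
                nes = area_nes(signatures, reg, min_targets, _quantiles=q)
            except ValueError:
                continue
            per_protein.setdefault(reg.regulator, []).append((net.context_id, nes))
    if not per_protein:
        raise ValueError("no regulon met the aREA size floor in any network")
    ids = sorted(per_protein)
    values = np.empty((len(ids), signatures.values.shape[1]))
    provenance = {}
    for i, prot in enumerate(ids):
        contexts, stack = zip(*per_protein[prot])
        nes = np.vstack(stack)
        if nes.shape[0] == 1:
            values[i] = nes[0]
        else:
            w = nes ** 2
            denom = np.sqrt(np.sum(w ** 2, axis=0))
            num = np.sum(w * nes, axis=0)
            values[i] = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        provenance[prot] = list(contexts)
    return ActivityMatrix(values, np.asarray(ids, dtype=object),
                          signatures.cell_ids.copy(), provenance)


def activity_to_norm(activity: ActivityMatrix) -> NormalizedMatrix:
    """View an ActivityMatrix as a normalized matrix for re-clustering."""
    params = pd.DataFrame(
        {"mean": activity.values.mean(axis=1), "nonzero": True},
        index=pd.Index(activity.protein_ids, name="gene"),
    )
    n_prot = len(activity.protein_ids)
    return NormalizedMatrix(
        activity.values.copy(), activity.protein_ids.copy(), activity.cell_ids.copy(),
        params, clip=np.inf, hvg_flags=np.ones(n_prot, dtype=bool),
    )


def master_regulators(
    activity: ActivityMatrix,
    labels: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrapped-t master-regulator ranking per cluster.

    For each cluster and protein, ``n_boot`` bootstrap resamples (cluster and
    rest resampled separately, with replacement) each yield a Welch t; the
    summary z is the studentized bootstrap mean, mean(t)/sd(t), with a
    two-sided normal p.  Proteins are ranked by decreasing z within cluster.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    x = activity.values
    rows = []
    for c in clusters:
        in_pos = np.flatnonzero(labels == c)
        out_pos = np.flatnonzero(labels != c)
        n_in, n_out = len(in_pos), len(out_pos)
        if n_in < 3 or n_out < 3:
            warnings.warn(f"cluster {c} too small for bootstrapped t; skipped")
            continue
        t_boot = np.empty((x.shape[0], n_boot))
        for b in range(n_boot):
            bi = in_pos[rng.integers(0, n_in, size=n_in)]
            bo = out_pos[rng.integers(0, n_out, size=n_out)]
            mi_, mo = x[:, bi].mean(axis=1), x[:, bo].mean(axis=1)
            vi = x[:, bi].var(axis=1, ddof=1)
            vo = x[:, bo].var(axis=1, ddof=1)
            se = np.sqrt(vi / n_in + vo / n_out)
            t_boot[:, b] = (mi_ - mo) / np.maximum(se, 1e-12)
        mean_t = t_boot.mean(axis=1)
        sd_t = np.maximum(t_boot.std(axis=1, ddof=1), 1e-8)
        z = mean_t / sd_t
        p = 2.0 * stats.norm.sf(np.abs(z))
        order = np.argsort(-z, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        for i, prot in enumerate(activity.protein_ids):
            rows.append((int(c), prot, mean_t[i], z[i], p[i], int(rank[i])))
    return pd.DataFrame(rows, columns=["cluster", "protein", "mean_boot_t",
                                       "stouffer_z", "p", "rank"])


def top_master_regulators(
    mr_table: pd.DataFrame, cluster: int, n: int = 100, positive_only: bool = True
) -> list[str]:
    """Top-n MRs of a cluster by decreasing z.

    By default only proteins with positive differential activity qualify: a
    cluster's master regulators are the proteins activated in it, and on a
    small protein universe an uncapped top-n would dip into anti-activated
    proteins and dilute downstream enrichment.
    """
    sub = mr_table[mr_table["cluster"] == cluster]
    if positive_only:
        sub = sub[sub["stouffer_z"] > 0]
    return sub.sort_values("rank")["protein"].head(n).tolist()
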