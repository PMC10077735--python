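"""Gene-set analyses: GSEA with leading-edge extraction, GSVA-style
per-cell scoring, and two-group comparison statistics.

GSEA uses the weighted Kolmogorov-Smirnov running sum (hit increments
proportional to |metric|^p, miss decrements 1/(N-n)) against a gene-set
permutation null: size-matched random sets drawn from the ranked universe,
with NES = ES divided by the mean |null ES| of matching sign.

GSVA estimates a per-gene expression level statistic across cells with a
Gaussian-kernel ECDF (bandwidth SD/4), ranks genes within each cell and
walks a KS-like statistic with centered rank weights.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GSEAResult:
    set_id: str
    es: float
    nes: float
    p_perm: float
    leading_edge: list[str]
    running_sum: np.ndarray

    @property
    def significant(self) -> bool:
        return abs(self.nes) > 1.0 and self.p_perm < 0.05


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_total: int) -> float:
    """ES extremum from sorted hit positions without the full running sum."""
    n = len(pos)
    miss = 1.0 / (n_total - n)
    cum_w = np.cumsum(weights)
    i = np.arange(n)
    dev_after = cum_w - (pos + 1 - (i + 1)) * miss
    dev_before = np.concatenate(([0.0], cum_w[:-1])) - (pos - i) * miss
    hi = dev_after.max() if len(dev_after) else 0.0
    lo = dev_before.min() if len(dev_before) else 0.0
    return float(hi if hi >= -lo else lo)


def gsea(
    ranked: pd.DataFrame,
    gene_set: set[str] | list[str],
    set_id: str = "set",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    metric_col: str = "log2FC",
    min_overlap: int = 5,
) -> GSEAResult:
    """Weighted-KS GSEA of one gene set against a ranked gene list.

    ``ranked`` must be ordered (descending metric); the null is ``n_perm``
    size-matched random gene sets, p = (1 + #{same-sign |null| >= |ES|}) /
    (n_perm + 1).
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked[metric_col].to_numpy(dtype=float)
    n_total = len(genes)
    members = set(gene_set)
    hit_mask = np.array([g in members for g in genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {set_id!r} has no member in the ranked universe")
    if n_hits < min_overlap:
        raise ValueError(
            f"gene set {set_id!r}: only {n_hits} members in universe (< {min_overlap})"
        )
    if n_hits == n_total:
        raise ValueError("gene set equals the whole universe; ES degenerate")

    pos = np.flatnonzero(hit_mask)
    raw_w = np.abs(metric[pos]) ** weight_p
    if raw_w.sum() == 0:
        raw_w = np.ones_like(raw_w)
    w = raw_w / raw_w.sum()

    # full running sum (exported for plotting elsewhere)
    steps = np.full(n_total, -1.0 / (n_total - n_hits))
    steps[pos] = w
    running = np.cumsum(steps)
    es = _es_from_positions(pos, w, n_total)

    rng = np.random.default_rng(seed)
    abs_metric_p = np.abs(metric) ** weight_p
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        rpos = np.sort(rng.choice(n_total, size=n_hits, replace=False))
        rw = abs_metric_p[rpos]
        if rw.sum() == 0:
            rw = np.ones_like(rw)
        null_es[b] = _es_from_positions(rpos, rw / rw.sum(), n_total)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
    # p is estimated within the sign-matched null, per the canonical recipe
    p = (1.0 + np.sum(np.abs(null_es[same_sign]) >= abs(es))) / (1.0 + int(same_sign.sum()))

    if es >= 0:
        peak = int(np.argmax(running))
        le = [g for g in genes[: peak + 1] if g in members]
    else:
        trough = int(np.argmin(running))
        le = [g for g in genes[trough:] if g in members]
    return GSEAResult(set_id, es, float(nes), float(p), le, running)


def intersect_leading_edges(le_sets: dict[str, set[str] | list[str]]) -> dict:
    """Exact intersection of named leading-edge sets.

    Both overlap denominators are reported: against each input set and
    against the union of all sets.
    """
    if len(le_sets) < 2:
        raise ValueError("need at least 2 leading-edge sets")
    sets = {k: set(v) for k, v in le_sets.items()}
    shared = set.intersection(*sets.values())
    union = set.union(*sets.values())
    return {
        "shared": shared,
        "n_shared": len(shared),
        "per_set_counts": {k: len(v) for k, v in sets.items()},
        "fraction_vs_each": {
            k: (len(shared) / len(v) if v else 0.0) for k, v in sets.items()
        },
        "fraction_vs_union": len(shared) / len(union) if union else 0.0,
    }


def gsva_scores(
    matrix: pd.DataFrame,
    gene_sets: dict[str, set[str] | list[str]],
    kcdf: str = "gaussian",
    mode: str = "max_diff",
    tau: float = 1.0,
) -> pd.DataFrame:
    """GSVA-style single-sample scores (pathways x cells).

    ``matrix`` is genes/proteins x cells.  Per gene a Gaussian-kernel ECDF
    (bandwidth SD/4) across cells gives an expression-level statistic; per
    cell, genes are ranked by it and a KS-like walk with centered-rank
    weights yields the score (max_diff: max positive + min negative
    deviation; classic: signed max |deviation|).
    """
    if kcdf != "gaussian":
        raise ValueError("only the gaussian kernel is implemented")
    if mode not in ("max_diff", "classic"):
        raise ValueError(f"unknown mode {mode!r}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant rows excluded from GSVA")
    x = x[keep]
    genes = matrix.index.to_numpy()[keep]
    n_genes, n_cells = x.shape

    z = np.empty_like(x)
    for gi in range(n_genes):
        h = sd[keep][gi] / 4.0
        z[gi] = stats.norm.cdf((x[gi][:, None] - x[gi][None, :]) / h).mean(axis=1)

    order = np.argsort(-z, axis=0, kind="stable")  # per cell, genes by z desc
    positions = np.empty_like(order)
    for c in range(n_cells):
        positions[order[:, c], c] = np.arange(n_genes)
    centered = np.abs(n_genes / 2.0 - (positions + 1) + 0.5) ** tau

    gidx = {g: i for i, g in enumerate(genes)}
    out = {}
    for name, members in gene_sets.items():
        idx = [gidx[m] for m in set(members) if m in gidx]
        if len(idx) < 3:
            warnings.warn(f"gene set {name!r} overlaps universe by <3 genes; skipped")
            continue
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[idx] = True
        scores = np.empty(n_cells)
        for c in range(n_cells):
            hits = in_set[order[:, c]]
            wts = centered[order[:, c], c]
            hit_w = np.where(hits, wts, 0.0)
            denom_hit = hit_w.sum()
            miss_step = 1.0 / (n_genes - len(idx))
            walk = np.cumsum(np.where(hits, hit_w / denom_hit, -miss_step))
            if mode == "max_diff":
                scores[c] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                scores[c] = walk.max() if walk.max() >= -walk.min() else walk.min()
        out[name] = scores
    if not out:
        raise ValueError("no gene set had sufficient overlap with the matrix")
    return pd.DataFrame(out, index=matrix.columns).T


def compare_groups(
    values: np.ndarray,
    labels: np.ndarray,
    test: str = "student_t",
) -> dict:
    """Two-group comparison (Student t or Mann-Whitney U), two-sided.

    A Shapiro normality pre-check (alpha = 0.05 per group) sets an advisory
    ``recommended_test`` field; degenerate variance for the t-test falls back
    to Mann-Whitney with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("labels must have exactly two groups")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    normal = True
    for g in (a, b):
        if len(g) >= 3 and np.std(g) > 0 and stats.shapiro(g).pvalue < 0.05:
            normal = False
    recommended = "student_t" if normal else "mann_whitney"

    used = test
    if test == "student_t":
        if np.std(a) == 0 and np.std(b) == 0:
            warnings.warn("degenerate variance: falling back to Mann-Whitney")
            used = "mann_whitney"
        else:
            res = stats.ttest_ind(a, b)
            return {"test": "student_t", "statistic": float(res.statistic),
                    "p": float(res.pvalue), "recommended_test": recommended}
    if used == "mann_whitney":
        method = "exact" if max(len(a), len(b)) <= 8 else "auto"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return {"test": "mann_whitney", "statistic": float(res.statistic),
                "p": float(res.pvalue), "recommended_test": recommended}
    raise ValueError(f"unknown test {test!r}")
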