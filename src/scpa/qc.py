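"""Per-cell quality control and variance-stabilizing normalization.

QC keeps cells with >= 1000 UMIs, 300-8000 expressed genes, <= 5% mitochondrial
UMIs and library complexity log10(n_gene)/log10(n_umi) >= 0.8 (all boundaries
inclusive on the keep side).

Normalization is a regularized negative-binomial Pearson-residual scheme:
per gene, an NB model with intercept and log-depth offset is fitted, the
per-gene dispersion is moment-estimated and then kernel-smoothed against the
gene mean, and clipped Pearson residuals are returned.  The 3000 genes with
the highest residual variance are flagged as highly variable.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "min_umi": 1000,
    "gene_range": (300, 8000),
    "max_mito": 5.0,
    "min_complexity": 0.8,
}


def compute_qc_metrics(counts: GeneExpressionMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: n_umi, n_gene, pct_mito, complexity, degenerate.

    ``complexity`` = log10(n_gene)/log10(n_umi), defined only for n_umi >= 2
    (NaN otherwise).  Cells with zero UMIs are flagged ``degenerate``.
    """
    mat = counts.counts.tocsc()
    if (mat.data < 0).any():
        raise ValueError("counts must be non-negative")
    n_umi = np.asarray(mat.sum(axis=0)).ravel()
    n_gene = np.asarray((mat > 0).sum(axis=0)).ravel()
    mito = counts.mito_mask()
    if not mito.any():
        warnings.warn("no 'MT-' genes present; pct_mito set to 0")
        mito_umi = np.zeros_like(n_umi)
    else:
        mito_umi = np.asarray(mat[mito, :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
        complexity = np.where(
            n_umi >= 2, np.log10(np.maximum(n_gene, 1)) / np.log10(np.maximum(n_umi, 2)), np.nan
        )
    return pd.DataFrame(
        {
            "n_umi": n_umi.astype(int),
            "n_gene": n_gene.astype(int),
            "pct_mito": pct_mito,
            "complexity": complexity,
            "degenerate": n_umi == 0,
        },
        index=pd.Index(counts.cell_ids, name="barcode"),
    )


def filter_cells(
    counts: GeneExpressionMatrix,
    metrics: pd.DataFrame | None = None,
    thresholds: dict | None = None,
) -> tuple[GeneExpressionMatrix, pd.DataFrame]:
    """Apply the QC rules; returns (retained matrix, per-rule removal report)."""
    if metrics is None:
        metrics = compute_qc_metrics(counts)
    if len(metrics) != counts.n_cells:
        raise ValueError("metrics must be computed on the same cells")
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    lo_g, hi_g = thr["gene_range"]

    pass_umi = metrics["n_umi"].to_numpy() >= thr["min_umi"]
    n_gene = metrics["n_gene"].to_numpy()
    pass_gene = (n_gene >= lo_g) & (n_gene <= hi_g)
    pass_mito = metrics["pct_mito"].to_numpy() <= thr["max_mito"]
    cplx = metrics["complexity"].to_numpy()
    pass_cplx = np.where(np.isnan(cplx), False, cplx >= thr["min_complexity"])
    keep = pass_umi & pass_gene & pass_mito & pass_cplx

    report = pd.DataFrame(
        {
            "rule": ["min_umi", "gene_range", "max_mito", "min_complexity", "any"],
            "removed": [
                int((~pass_umi).sum()),
                int((~pass_gene).sum()),
                int((~pass_mito).sum()),
                int((~pass_cplx).sum()),
                int((~keep).sum()),
            ],
            "retained": [int(p.sum()) for p in (pass_umi, pass_gene, pass_mito, pass_cplx, keep)],
        }
    )
    for _, row in report.iterrows():
        log.info("QC %-15s removed=%d retained=%d", row["rule"], row["removed"], row["retained"])
    if not keep.any():
        raise ValueError("QC removed every cell")
    return counts.subset_cells(keep), report


@dataclass
class NormalizedMatrix:
    """Clipped NB Pearson residuals with per-gene model parameters."""

    values: np.ndarray                   # genes x cells
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    model_params: pd.DataFrame           # per gene: mean, theta_raw, theta
    clip: float
    hvg_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.hvg_flags is None:
            self.hvg_flags = np.zeros(len(self.gene_ids), dtype=bool)

    def hvg_view(self) -> "NormalizedMatrix":
        keep = self.hvg_flags
        return NormalizedMatrix(
            self.values[keep], self.gene_ids[keep], self.cell_ids,
            self.model_params.loc[self.gene_ids[keep]], self.clip,
            np.ones(int(keep.sum()), dtype=bool),
        )


def _kernel_smooth(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, bw: float) -> np.ndarray:
    """Nadaraya-Watson Gaussian-kernel regression of y on x."""
    out = np.empty_like(x_eval, dtype=float)
    for i, xe in enumerate(x_eval):
        w = np.exp(-0.5 * ((x - xe) / bw) ** 2)
        sw = w.sum()
        out[i] = (w @ y) / sw if sw > 0 else y.mean()
    return out


def normalize_pearson_residuals(
    counts: GeneExpressionMatrix,
    theta_bandwidth: float = 0.3,
    theta_max: float = 1e6,
) -> NormalizedMatrix:
    """Regularized-NB Pearson residuals, clipped to +/- sqrt(n_cells).

    Per gene g and cell c the model mean is mu_gc = exp(beta0_g) * n_umi_c
    (intercept plus log-depth offset; beta0 has the closed-form Poisson MLE).
    The dispersion theta_g is moment-estimated and then smoothed against
    log10 gene mean by Gaussian-kernel regression.
    """
    if counts.n_cells < 2:
        raise ValueError("need at least 2 cells")
    x = counts.to_dense().astype(float)
    n_genes, n_cells = x.shape
    depth = x.sum(axis=0)
    if (depth == 0).any():
        raise ValueError("cells with zero counts must be removed before normalization")
    gene_tot = x.sum(axis=1)
    nonzero = gene_tot > 0

    mu = np.zeros_like(x)
    beta0 = np.full(n_genes, -np.inf)
    beta0[nonzero] = np.log(gene_tot[nonzero] / depth.sum())
    mu[nonzero] = np.exp(beta0[nonzero])[:, None] * depth[None, :]

    # moment estimator: E[(x-mu)^2] = mu + mu^2/theta
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = ((x - mu) ** 2 - mu).sum(axis=1)
        mu_sq = (mu ** 2).sum(axis=1)
        theta_raw = np.where(excess > 0, mu_sq / np.maximum(excess, 1e-12), theta_max)
    theta_raw = np.clip(theta_raw, 1e-4, theta_max)

    gene_mean = np.where(nonzero, gene_tot / n_cells, np.nan)
    log_mean = np.log10(np.maximum(gene_mean, 1e-12))
    theta = np.full(n_genes, theta_max)
    if nonzero.sum() >= 2:
        sm = _kernel_smooth(
            log_mean[nonzero], np.log10(theta_raw[nonzero]), log_mean[nonzero], theta_bandwidth
        )
        theta[nonzero] = np.clip(10.0 ** sm, 1e-4, theta_max)

    clip = float(np.sqrt(n_cells))
    resid = np.zeros_like(x)
    denom = np.sqrt(mu[nonzero] + mu[nonzero] ** 2 / theta[nonzero][:, None])
    resid[nonzero] = np.clip((x[nonzero] - mu[nonzero]) / denom, -clip, clip)

    params = pd.DataFrame(
        {"mean": gene_mean, "beta0": beta0, "theta_raw": theta_raw, "theta": theta,
         "nonzero": nonzero},
        index=pd.Index(counts.gene_ids, name="gene"),
    )
    return NormalizedMatrix(resid, counts.gene_ids.copy(), counts.cell_ids.copy(), params, clip)


def select_hvg(norm: NormalizedMatrix, n: int = 3000) -> np.ndarray:
    """Flag the top-n genes by residual variance (ties: lexicographic gene id).

    Genes with zero total count are excluded from the ranking.
    """
    variances = norm.values.var(axis=1)
    eligible = norm.model_params["nonzero"].to_numpy()
    if n >= int(eligible.sum()):
        if n > int(eligible.sum()):
            warnings.warn("n exceeds number of expressed genes; flagging all")
        flags = eligible.copy()
    else:
        order = sorted(
            np.flatnonzero(eligible), key=lambda i: (-variances[i], str(norm.gene_ids[i]))
        )
        flags = np.zeros(len(norm.gene_ids), dtype=bool)
        flags[order[:n]] = True
    norm.hvg_flags = flags
    return flags


def standardize_per_sample(
    norm: NormalizedMatrix, sample_labels: np.ndarray
) -> NormalizedMatrix:
    """Optional cross-sample harmonization: z-score each gene within each sample.

    Off by default in the pipeline; a light-weight stand-in for anchor-based
    integration when batch structure is present.
    """
    values = norm.values.copy()
    labels = np.asarray(sample_labels)
    for s in np.unique(labels):
        cols = labels == s
        block = values[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        values[:, cols] = np.where(sd > 0, (block - mean) / np.maximum(sd, 1e-12), 0.0)
    return NormalizedMatrix(
        values, norm.gene_ids, norm.cell_ids, norm.model_params, norm.clip, norm.hvg_flags
    )
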