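"""Bulk RNA-seq normalization, differential expression and qPCR utilities.

Normalization is TMM (trimmed mean of M-values) followed by log2 CPM.
Differential expression is a simplified voom/eBayes chain: mean-variance
precision weights from a lowess trend of sqrt(residual SD) against average
log2 count, weighted least-squares group contrasts, and empirical-Bayes
variance moderation with a moment-matched prior.  Genes pass when
|log2FC| > 1 and the BH-adjusted p is below 0.05.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

LOG2FC_CUTOFF = 1.0
ADJ_P_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# TMM + log2 CPM

def _tmm_factor_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     m_trim: float = 0.30, a_trim: float = 0.05) -> float:
    """log2 TMM factor of one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 0.0
    o, r = obs[ok], ref[ok]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    if len(m) == 0:
        return 0.0
    m_lo, m_hi = np.quantile(m, [m_trim, 1.0 - m_trim])
    a_lo, a_hi = np.quantile(a, [a_trim, 1.0 - a_trim])
    keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not keep.any():
        return 0.0
    w = 1.0 / np.maximum(v[keep], 1e-12)
    f = float(np.sum(w * m[keep]) / np.sum(w))
    return f if abs(f) > 1e-10 else 0.0


def tmm_log2cpm(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """TMM normalization factors and log2(CPM + 0.5) matrix.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper quartile; factors are scaled to geometric
    mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        zero = counts.columns[lib == 0].tolist()
        raise ValueError(f"zero-library samples: {zero}")
    uq = np.array([np.quantile(x[x[:, j] > 0, j] / lib[j], 0.75) if (x[:, j] > 0).any() else 0
                   for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    log2f = np.array([
        0.0 if j == ref else _tmm_factor_pair(x[:, j], x[:, ref], lib[j], lib[ref])
        for j in range(x.shape[1])
    ])
    factors = 2.0 ** log2f
    factors /= np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    cpm = x / eff_lib[None, :] * 1e6
    log2cpm = np.log2(cpm + 0.5)
    return (
        pd.Series(factors, index=counts.columns, name="norm_factor"),
        pd.DataFrame(log2cpm, index=counts.index, columns=counts.columns),
    )


# ---------------------------------------------------------------------------
# voom/eBayes-lite differential expression

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (limma-style)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _moment_match_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-matched prior df and variance for variance shrinkage."""
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_var = np.var(e, ddof=1) - special.polygamma(1, df_resid / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s0_sq = np.exp(np.mean(e))
    else:
        d0 = 2.0 * _trigamma_inverse(float(e_var))
        s0_sq = np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Two-group moderated differential expression on bulk counts.

    Returns a table with log2FC (contrast group minus ``baseline``; the first
    sorted label if unspecified), moderated t, p, BH-adjusted p, and the
    ``passes`` flag (|log2FC| > 1 and p_adj < 0.05).
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("groups must have exactly two levels")
    if baseline is not None:
        if baseline not in levels:
            raise ValueError(f"baseline {baseline!r} not among group labels {levels}")
        levels = [baseline] + [lv for lv in levels if lv != baseline]
    g1, g2 = levels
    n1, n2 = int((groups == g1).sum()), int((groups == g2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    _, log2cpm = tmm_log2cpm(counts)
    y = log2cpm.to_numpy()
    design = (groups == g2).to_numpy().astype(float)  # 0/1 indicator
    n = y.shape[1]
    df_resid = n - 2

    # first pass: unweighted fit for the mean-variance trend
    m1 = y[:, design == 0].mean(axis=1)
    m2 = y[:, design == 1].mean(axis=1)
    fitted = np.where(design[None, :] == 1, m2[:, None], m1[:, None])
    resid = y - fitted
    s = np.sqrt(np.maximum((resid ** 2).sum(axis=1) / df_resid, 1e-12))
    mean_log_count = y.mean(axis=1)
    trend = lowess(np.sqrt(s), mean_log_count, frac=0.5, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    pred_sqrt_sd = np.interp(fitted, tx, ty)
    w = 1.0 / pred_sqrt_sd ** 4

    # weighted two-group fit per gene
    w1 = np.where(design[None, :] == 0, w, 0.0)
    w2 = np.where(design[None, :] == 1, w, 0.0)
    sw1, sw2 = w1.sum(axis=1), w2.sum(axis=1)
    mu1 = (w1 * y).sum(axis=1) / sw1
    mu2 = (w2 * y).sum(axis=1) / sw2
    log2fc = mu2 - mu1
    fitted_w = np.where(design[None, :] == 1, mu2[:, None], mu1[:, None])
    s2 = (w * (y - fitted_w) ** 2).sum(axis=1) / df_resid
    unscaled_se = np.sqrt(1.0 / sw1 + 1.0 / sw2)

    d0, s0_sq = _moment_match_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e6
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    t_mod = log2fc / (np.sqrt(s2_post) * unscaled_se)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": counts.index,
            "log2FC": log2fc,
            "t_moderated": t_mod,
            "p": p,
            "p_adj_BH": p_adj,
        }
    )
    table["passes"] = (np.abs(table["log2FC"]) > LOG2FC_CUTOFF) & (table["p_adj_BH"] < ADJ_P_CUTOFF)
    return table


def rank_genes(deg: pd.DataFrame, deg_only: bool = False) -> pd.DataFrame:
    """Rank genes by descending log2FC (ties: t, then gene id) for GSEA.

    By default the full list is ranked; ``deg_only`` restricts to passing
    genes.
    """
    table = deg[deg["passes"]] if deg_only else deg
    ranked = table.sort_values(
        ["log2FC", "t_moderated", "gene"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    return ranked[["gene", "log2FC", "t_moderated"]]


# ---------------------------------------------------------------------------
# qPCR and probe utilities

def delta_delta_ct(ct: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` columns: sample, condition, target_ct, reference_ct; replicate
    rows per sample are averaged before dCt.  dCt = target - reference;
    ddCt = dCt - mean(dCt of the control condition); fold = 2^-ddCt.
    """
    required = {"sample", "condition", "target_ct", "reference_ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    rows = []
    for (sample, cond), sub in ct.groupby(["sample", "condition"], sort=False):
        if sub["reference_ct"].isna().all() or sub["target_ct"].isna().all():
            warnings.warn(f"sample {sample!r} missing Ct values; dropped")
            continue
        rows.append((sample, cond,
                     float(sub["target_ct"].mean()) - float(sub["reference_ct"].mean())))
    d = pd.DataFrame(rows, columns=["sample", "condition", "delta_ct"])
    control = d.loc[d["condition"] == control_condition, "delta_ct"]
    if control.empty:
        raise ValueError(f"no samples in control condition {control_condition!r}")
    d["delta_delta_ct"] = d["delta_ct"] - control.mean()
    d["fold_change"] = 2.0 ** (-d["delta_delta_ct"])
    return d


def collapse_probes(expr: pd.DataFrame, probe_to_genes: dict[str, list[str] | str]) -> pd.DataFrame:
    """Collapse probe-level rows to gene symbols.

    Probes mapping to multiple genes are dropped; multiple probes for one
    gene are averaged.
    """
    keep_rows: dict[str, list[str]] = {}
    for probe in expr.index:
        genes = probe_to_genes.get(probe)
        if genes is None:
            continue
        if isinstance(genes, str):
            genes = [genes]
        if len(genes) != 1:
            continue
        keep_rows.setdefault(genes[0], []).append(probe)
    out = {g: expr.loc[probes].mean(axis=0) for g, probes in keep_rows.items()}
    return pd.DataFrame(out).T.sort_index()
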