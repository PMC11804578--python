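"""Reduced negative-binomial differential-expression engine.

A deliberately small NB Wald workflow in the DESeq2 mould: median-of-ratios
size factors, method-of-moments gene dispersions shrunk toward a 1/mu trend,
closed-form condition means (the MLE of an NB mean under a cell-means model
is the sample mean of normalized counts), and a Wald test on
log2(mu_num / mu_den). There is no Cox-Reid adjustment and no fold-change
shrinkage; downstream acceptance is by statistical calibration and planted
signal recovery, not numerical identity with any particular package.

Two designs are supported per contrast:

- unpaired (cell means): used for between-population and between-experiment
  comparisons, mirroring the single combined population+treatment factor
  model;
- paired: treatment-vs-control within a population with individuals matched
  across treatments; the statistic is the mean per-individual log-ratio,
  which removes additive individual effects exactly (the within-population
  individual blocking of the nested design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix

_LN2 = np.log(2.0)
_MEAN_FLOOR = 0.5  # floor for normalized condition means in log fold changes


def median_ratio_size_factors(
    cm: CountMatrix, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those with no zero count; each sample's factor is the
    median over reference genes of count / (gene geometric mean). With
    ``pseudo_reference=True`` the geometric mean is taken over a gene's
    positive counts only, rescuing datasets where no gene is all-positive.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        npos = np.sum(counts > 0, axis=1)
        ref = npos > 0
        geo = np.exp(np.nanmean(logc, axis=1, where=~np.isnan(logc)))
    else:
        ref = (counts > 0).all(axis=1)
        if not ref.any():
            raise ValueError(
                "no gene has all-positive counts; rerun with pseudo_reference=True"
            )
        geo = np.exp(np.mean(np.log(np.where(counts > 0, counts, 1.0)), axis=1))
    ratios = counts[ref] / geo[ref, None]
    if pseudo_reference:
        ratios = np.where(counts[ref] > 0, ratios, np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        factors = np.median(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("non-positive size factor computed")
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, nf: pd.Series) -> pd.DataFrame:
    return cm.counts / nf.loc[cm.sample_ids]


def estimate_dispersions(
    cm: CountMatrix,
    nf: pd.Series,
    groups: pd.Series,
    shrink_prior_df: float = 4.0,
) -> pd.DataFrame:
    """Method-of-moments NB dispersions shrunk toward an a0 + a1/mu trend.

    Per gene: pooled within-group variance s2 and overall normalized mean m
    give alpha_mom = max(0, (s2 - m) / m^2). A least-squares trend
    alpha(mu) = a0 + a1/mu is fitted on positive estimates and each gene's
    final dispersion is w * alpha_mom + (1 - w) * trend with
    w = df / (df + shrink_prior_df), df = n_samples - n_groups.
    """
    groups = groups.loc[cm.sample_ids]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with < 2 samples: {small}")
    norm = normalized_counts(cm, nf)
    num = np.zeros(cm.shape[0])
    for g, cols in groups.groupby(groups).groups.items():
        sub = norm[list(cols)]
        num += sub.var(axis=1, ddof=1).to_numpy() * (len(cols) - 1)
    df_within = len(groups) - len(sizes)
    s2 = num / df_within
    mean = norm.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mean > 0, (s2 - mean) / mean**2, 0.0)
    alpha_mom = np.clip(alpha_mom, 0.0, None)

    pos = (alpha_mom > 0) & (mean > 0)
    if pos.sum() >= 2:
        X = np.column_stack([np.ones(pos.sum()), 1.0 / mean[pos]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[pos], rcond=None)
        a0, a1 = coef
        with np.errstate(divide="ignore"):
            trend = a0 + a1 / np.where(mean > 0, mean, np.inf)
    else:
        trend = np.full_like(alpha_mom, alpha_mom.mean())
    trend = np.clip(trend, 1e-8, None)

    w = df_within / (df_within + shrink_prior_df)
    alpha = w * alpha_mom + (1.0 - w) * trend
    return pd.DataFrame(
        {"alpha_mom": alpha_mom, "alpha_trend": trend, "alpha": alpha},
        index=cm.gene_ids,
    )


def _cell_stats(norm: pd.DataFrame, nf: pd.Series, cols: list[str]):
    """Mean of normalized counts and its delta-method log2 variance factor."""
    mu = norm[cols].mean(axis=1).to_numpy()
    mu_f = np.maximum(mu, _MEAN_FLOOR)
    inv_s = float(np.sum(1.0 / nf.loc[cols].to_numpy()))
    n = len(cols)
    return mu, mu_f, inv_s, n


def nb_wald_contrast(
    cm: CountMatrix,
    nf: pd.Series,
    disp: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
    paired_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of condition ``contrast[0]`` over ``contrast[1]``.

    Returns a DataFrame with gene_id, log2fc, se, pvalue (unadjusted).
    Genes with all-zero counts in both conditions get log2fc = 0, p = 1.
    """
    num_cond, den_cond = contrast
    design = design.loc[design.index.intersection(cm.sample_ids)]
    num_cols = [s for s in cm.sample_ids if design.get(s) == num_cond]
    den_cols = [s for s in cm.sample_ids if design.get(s) == den_cond]
    if not num_cols or not den_cols:
        raise ValueError(f"contrast conditions {contrast} not both present in design")
    norm = normalized_counts(cm, nf)
    alpha = disp["alpha"].loc[cm.gene_ids].to_numpy()

    if paired_by is None:
        mu_n, mu_nf, inv_s_n, n_n = _cell_stats(norm, nf, num_cols)
        mu_d, mu_df, inv_s_d, n_d = _cell_stats(norm, nf, den_cols)
        log2fc = np.log2(mu_nf) - np.log2(mu_df)
        var = (
            (inv_s_n / mu_nf + n_n * alpha) / n_n**2
            + (inv_s_d / mu_df + n_d * alpha) / n_d**2
        ) / _LN2**2
        se = np.sqrt(var)
        allzero = (mu_n == 0) & (mu_d == 0)
    else:
        pairs = _match_pairs(paired_by, num_cols, den_cols)
        mu_n = norm[[a for a, _ in pairs]].mean(axis=1).to_numpy()
        mu_d = norm[[b for _, b in pairs]].mean(axis=1).to_numpy()
        mu_nf, mu_df = np.maximum(mu_n, _MEAN_FLOOR), np.maximum(mu_d, _MEAN_FLOOR)
        n = len(pairs)
        d_sum = np.zeros(cm.shape[0])
        var_sum = np.zeros(cm.shape[0])
        for a, b in pairs:
            na = np.maximum(norm[a].to_numpy(), _MEAN_FLOOR)
            nb = np.maximum(norm[b].to_numpy(), _MEAN_FLOOR)
            d_sum += np.log2(na) - np.log2(nb)
            var_sum += (
                1.0 / (nf.loc[a] * mu_nf)
                + 1.0 / (nf.loc[b] * mu_df)
                + 2.0 * alpha
            ) / _LN2**2
        log2fc = d_sum / n
        se = np.sqrt(var_sum) / n
        allzero = (mu_n == 0) & (mu_d == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(allzero, 0.0, log2fc)
    pvalue = np.where(allzero, 1.0, pvalue)
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
        }
    ).reset_index(drop=True)


def _match_pairs(paired_by: pd.Series, num_cols: list[str], den_cols: list[str]):
    by_num = {paired_by.loc[s]: s for s in num_cols}
    by_den = {paired_by.loc[s]: s for s in den_cols}
    if set(by_num) != set(by_den) or len(by_num) != len(num_cols) or len(by_den) != len(den_cols):
        raise ValueError(
            "paired contrast requires exactly one sample per individual per condition"
        )
    return [(by_num[i], by_den[i]) for i in sorted(by_num)]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_genes(res: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Ternary direction calls from a DE result table.

    Adds ``padj`` (BH over exactly the rows present) if absent, and a
    ``call`` column: up/down when padj <= alpha and log2fc is non-zero with
    the matching sign, ns otherwise.
    """
    out = res.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    sig = out["padj"].to_numpy() <= alpha
    lfc = out["log2fc"].to_numpy()
    call = np.where(sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns"))
    out["call"] = call
    return out
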