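"""Conditional enrichment/depletion of mutants: NB GLM with a Wald test.

Per-gene read counts across samples are normalised by median-of-ratios size
factors, overdispersion is estimated by a method-of-moments gene-wise
estimator shrunk toward a mean-dispersion trend, and each gene is fitted
with a negative-binomial generalized linear model (log link, size-factor
offsets) for a two-group contrast (reference library vs selected library).
The Wald statistic log2FC / SE gives a two-sided normal p-value, adjusted by
Benjamini-Hochberg at alpha = 0.1.

This is a deliberately simplified take on the standard count-based
differential pipeline: no empirical-Bayes dispersion prior, no outlier
refitting, no independent filtering, no LFC shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))


# --------------------------------------------------------------- count matrix

def build_count_matrix(profiles_by_sample: Mapping[str, Mapping[str, object]],
                       essential_gene_ids: Iterable[str] = ()) -> pd.DataFrame:
    """Gene x sample matrix of summed read counts of surviving insertions.

    ``profiles_by_sample`` maps sample -> {gene_id -> GeneInsertionProfile}
    (already filtered). Putatively essential genes are excluded from the
    matrix. Raises ValueError when a sample has zero total counts.
    """
    excluded = set(essential_gene_ids)
    data = {}
    for sample, profiles in profiles_by_sample.items():
        col = {
            gid: sum(rc for _, _, rc in p.insertions)
            for gid, p in profiles.items() if gid not in excluded
        }
        data[sample] = col
    counts = pd.DataFrame(data).fillna(0).astype(int).sort_index()
    zero = counts.sum(axis=0) == 0
    if zero.any():
        raise ValueError(f"samples with zero counts: {list(counts.columns[zero])}")
    return counts


# --------------------------------------------------------------- size factors

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation.

    s_j = median over reference genes of count_ij / geometric-mean_i, using
    only genes whose counts are positive in every sample (finite log
    geometric mean). Row-permutation invariant.
    """
    mat = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValueError("no gene has positive counts in every sample")
    log_geomean = logs[finite].mean(axis=1)
    sf = np.exp(np.median(logs[finite] - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------- dispersions

def _trend_fit(mu: np.ndarray, alpha: np.ndarray,
               n_iter: int = 10) -> tuple[float, float]:
    """Robust fit of the dispersion trend alpha(mu) = a1/mu + a0 by
    iteratively trimmed least squares (drop points > 3 MAD from the fit)."""
    x = np.column_stack([np.ones_like(mu), 1.0 / mu])
    keep = np.ones(len(mu), bool)
    a0 = a1 = 0.0
    for _ in range(n_iter):
        coef, *_ = np.linalg.lstsq(x[keep], alpha[keep], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
        resid = alpha - (a0 + a1 / mu)
        scale = np.median(np.abs(resid)) * 1.4826
        new_keep = np.abs(resid) <= 3 * max(scale, 1e-12)
        if new_keep.sum() < 5 or (new_keep == keep).all():
            break
        keep = new_keep
    return max(a0, 0.0), max(a1, 0.0)


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series,
                         conditions: Mapping[str, str] | pd.Series,
                         shrink_weight: float = 0.5,
                         min_alpha: float = 1e-8) -> pd.DataFrame:
    """Per-gene NB dispersion: method-of-moments within conditions, a
    parametric trend over the mean, and geometric-mean shrinkage.

    For each gene, normalised counts q = k/s give within-condition mean m
    and variance v; alpha_mom = (v - m)/m^2 clipped at 0, pooled across
    conditions with (n_c - 1) weights. The trend a1/mu + a0 is fitted
    robustly over genes with positive estimates, and the final value is
    exp(w*log(trend) + (1-w)*log(gene-wise)) with gene-wise values floored
    at ``min_alpha``. All-zero genes are skipped (NaN).
    """
    cond = pd.Series(conditions).reindex(counts.columns)
    q = counts.to_numpy(float) / sf.reindex(counts.columns).to_numpy(float)

    mu = q.mean(axis=1)
    alpha_gene = np.zeros(len(counts))
    weight_sum = np.zeros(len(counts))
    for c in cond.unique():
        cols = np.flatnonzero((cond == c).to_numpy())
        if cols.size < 2:
            continue
        qc = q[:, cols]
        m = qc.mean(axis=1)
        v = qc.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, np.nan)
        a = np.clip(a, 0.0, None)
        w = cols.size - 1
        ok = np.isfinite(a)
        alpha_gene[ok] += w * a[ok]
        weight_sum[ok] += w
    with np.errstate(invalid="ignore"):
        alpha_gene = np.where(weight_sum > 0, alpha_gene / np.maximum(weight_sum, 1), np.nan)

    usable = np.isfinite(alpha_gene) & (mu > 0)
    fit_mask = usable & (alpha_gene > 0)
    if fit_mask.sum() >= 5:
        a0, a1 = _trend_fit(mu[fit_mask], alpha_gene[fit_mask])
    else:  # too few informative genes: flat fallback trend
        a0, a1 = float(np.nanmedian(alpha_gene[usable])) if usable.any() else 0.0, 0.0
    alpha_trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), np.nan)

    # gene-wise values below the trend are floored at it before shrinking:
    # with few replicates a low method-of-moments estimate is noise, and
    # letting it pull the final dispersion toward zero makes the Wald test
    # anti-conservative
    floored = np.maximum(alpha_gene, np.where(np.isfinite(alpha_trend),
                                              alpha_trend, 0.0))
    log_final = (shrink_weight * np.log(np.maximum(alpha_trend, min_alpha))
                 + (1 - shrink_weight) * np.log(np.maximum(floored, min_alpha)))
    alpha_final = np.where(usable, np.exp(log_final), np.nan)

    return pd.DataFrame({
        "base_mean": mu,
        "alpha_gene": alpha_gene,
        "alpha_trend": alpha_trend,
        "alpha": alpha_final,
    }, index=counts.index)


# ------------------------------------------------------------------- NB GLM

def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float,
             max_iter: int = 50, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit an NB GLM with log link by iteratively reweighted least squares.

    Returns (beta, covariance of beta, converged); weights are the Fisher
    weights mu/(1 + alpha*mu) of the NB variance function mu + alpha*mu^2.
    """
    beta = np.zeros(x.shape[1])
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    converged = False
    for _ in range(max_iter):
        eta = offset + x @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = x.T * w
        a = xtw @ x
        b = xtw @ z
        try:
            new_beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return beta, np.full((x.shape[1], x.shape[1]), np.nan), False
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    eta = offset + x @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    info = (x.T * w) @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((x.shape[1], x.shape[1]), np.nan)
    return beta, cov, converged


def wald_test(counts: pd.DataFrame, sf: pd.Series, dispersions: pd.DataFrame,
              conditions: Mapping[str, str] | pd.Series,
              reference: str, treatment: str | None = None) -> pd.DataFrame:
    """Per-gene two-group NB Wald test (treatment vs reference).

    log2 fold change and its standard error come from the NB GLM fit with
    size-factor offsets; the two-sided p-value is normal on the Wald
    statistic. Genes with zero counts throughout one group get a 0.5-count
    continuity correction before fitting and are flagged ``zero_group``.
    Non-converged fits keep their estimate but report a missing p-value.
    """
    cond = pd.Series(conditions).reindex(counts.columns)
    if treatment is None:
        others = [c for c in cond.unique() if c != reference]
        if len(others) != 1:
            raise ValueError("two-group design required; pass `treatment`")
        treatment = others[0]
    cols = cond.isin([reference, treatment])
    cond = cond[cols]
    sub = counts.loc[:, cond.index]
    x = np.column_stack([
        np.ones(cond.size),
        (cond == treatment).to_numpy(float),
    ])
    offset = np.log(sf.reindex(cond.index).to_numpy(float))
    alphas = dispersions["alpha"].reindex(sub.index).to_numpy(float)

    ref_cols = (cond == reference).to_numpy()
    trt_cols = ~ref_cols
    rows = []
    for gi, (gene, y) in enumerate(zip(sub.index, sub.to_numpy(float))):
        alpha = alphas[gi]
        if not np.isfinite(alpha):
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        zero_group = (y[ref_cols].sum() == 0) or (y[trt_cols].sum() == 0)
        yfit = y + 0.5 if zero_group else y
        beta, cov, converged = _nb_irls(yfit, x, offset, alpha)
        lfc = beta[1] / LN2
        se = np.sqrt(cov[1, 1]) / LN2 if np.isfinite(cov[1, 1]) else np.nan
        stat = lfc / se if se and np.isfinite(se) and se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(stat)) if converged and np.isfinite(stat) else np.nan
        rows.append((gene, lfc, se, stat, p, zero_group, converged))

    out = pd.DataFrame(rows, columns=[
        "gene_id", "log2FoldChange", "lfcSE", "stat", "pvalue",
        "zero_group", "converged",
    ]).set_index("gene_id")
    out.insert(0, "baseMean", dispersions["base_mean"].reindex(out.index))
    return out


# ---------------------------------------------------------------- adjustment

def bh_adjust(results: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted p-values and enrichment/depletion calls.

    significant <=> padj <= alpha; call is 'enriched' for positive log2FC,
    'depleted' for negative, 'ns' otherwise. Missing p-values stay missing.
    """
    out = results.copy()
    out["padj"] = np.nan
    ok = out["pvalue"].notna().to_numpy()
    if ok.any():
        _, padj, _, _ = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")
        out.loc[ok, "padj"] = padj
    sig = out["padj"] <= alpha
    out["call"] = np.where(
        sig & (out["log2FoldChange"] > 0), "enriched",
        np.where(sig & (out["log2FoldChange"] < 0), "depleted", "ns"),
    )
    return out


def run_differential(counts: pd.DataFrame,
                     conditions: Mapping[str, str] | pd.Series,
                     reference: str, treatment: str | None = None,
                     alpha: float = 0.1,
                     shrink_weight: float = 0.5) -> pd.DataFrame:
    """Size factors -> dispersions -> Wald test -> BH, in one call."""
    sf = size_factors(counts)
    disp = estimate_dispersions(counts, sf, conditions, shrink_weight=shrink_weight)
    res = wald_test(counts, sf, disp, conditions, reference, treatment)
    return bh_adjust(res, alpha=alpha)
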