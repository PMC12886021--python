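"""Negative-binomial differential expression and stage-trend testing.

A desk-scale NB Wald workflow in the DESeq2 mould: median-of-ratios size
factors, a per-miRNA NB GLM (log link, intercept + condition, log size
factors as offsets) with a method-of-moments dispersion estimate, a Wald
z-test on the condition coefficient, and Benjamini-Hochberg adjustment at
adjusted p < 0.1 with no fold-change threshold.  The empirical-Bayes
machinery of DESeq2 (dispersion shrinkage, Cook's filtering, independent
filtering) is deliberately not reproduced; what matters here is calibration
(near-uniform null p-values, FDR control), not value-identity with DESeq2.

The stage-trend test is a per-miRNA Spearman rank correlation between CPM
values and an ordinal stage coding (HR=0, I=1, II=2, III=3, IV=4; substages
merged; stage-0 samples excluded as too rare to order reliably).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_STAGE_CODING = {
    "none": 0,  # HR baseline
    "IA": 1, "IB": 1,
    "IIA": 2, "IIB": 2,
    "III": 3,
    "IV": 4,
}


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample: the exponentiated median over all-nonzero miRNAs of
    ``log(count) - log(geometric row mean)``.  Rows with any zero are
    excluded from the reference, as in DESeq2.
    """
    x = counts.to_numpy(dtype=float)
    usable = (x > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no miRNA is nonzero in every sample; size factors undefined "
            "(consider a poscounts-style fallback)")
    logs = np.log(x[usable])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _mom_dispersion(y: np.ndarray, sf: np.ndarray, groups: np.ndarray,
                    floor: float = 1e-8) -> float:
    """Method-of-moments dispersion, pooled over the two groups.

    ``Var(K/s) = mu/s + alpha*mu^2`` per sample, so within each group
    ``alpha ~ (var(z) - mean(z)*mean(1/s)) / mean(z)^2`` with ``z = K/s``.
    """
    z = y / sf
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        zg = z[groups == g]
        sg = sf[groups == g]
        if len(zg) < 2 or zg.mean() <= 0:
            continue
        m = zg.mean()
        v = zg.var(ddof=1)
        w = len(zg) - 1
        num += w * (v - m * np.mean(1.0 / sg))
        den += w * m * m
    if den <= 0:
        return floor
    return max(num / den, floor)


def nb_wald_de(counts: pd.DataFrame, condition, alpha: float = 0.1,
               size_factors: pd.Series | None = None,
               dispersion_floor: float = 1e-8) -> pd.DataFrame:
    """Per-miRNA NB Wald test between two conditions.

    ``condition`` is a binary vector over the samples (0 = reference,
    1 = contrast); the reported ``log2_fold_change`` is contrast vs
    reference.  Returns a DataFrame indexed by miRNA with ``base_mean``,
    ``log2_fold_change``, ``wald_stat``, ``p_value``, ``adj_p``,
    ``significant`` and a ``degenerate`` flag for rows where no fit was
    possible (all-zero counts); those rows get p = 1 and lfc = 0.
    """
    cond = np.asarray(condition)
    if set(np.unique(cond)) - {0, 1}:
        raise ValueError("condition must be binary 0/1")
    if len(cond) != counts.shape[1]:
        raise ValueError("condition length must match the number of samples")
    if cond.sum() == 0 or cond.sum() == len(cond):
        raise ValueError("both groups must be non-empty")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(sf)
    design = sm.add_constant(cond.astype(float))

    rows = []
    for mirna, y in counts.iterrows():
        y = y.to_numpy(dtype=float)
        base_mean = float((y / sf).mean())
        if y.sum() == 0:
            rows.append((mirna, 0.0, 0.0, 0.0, 1.0, True))
            continue
        disp = _mom_dispersion(y, sf, cond, dispersion_floor)
        try:
            fit = sm.GLM(y, design, offset=offset,
                         family=sm.families.NegativeBinomial(alpha=disp)
                         ).fit(maxiter=100)
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            if not np.isfinite(se) or se <= 0:
                raise ValueError("non-finite standard error")
            z = beta / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((mirna, base_mean, beta / np.log(2), z, p, False))
        except Exception:
            rows.append((mirna, base_mean, 0.0, 0.0, 1.0, True))
    res = pd.DataFrame(
        rows, columns=["mirna", "base_mean", "log2_fold_change",
                       "wald_stat", "p_value", "degenerate"],
    ).set_index("mirna")
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    res["significant"] = res["adj_p"] < alpha
    return res[["base_mean", "log2_fold_change", "wald_stat", "p_value",
                "adj_p", "significant", "degenerate"]]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def spearman_stage_trend(cpm: pd.DataFrame, meta: pd.DataFrame,
                         stage_coding: dict | None = None) -> pd.DataFrame:
    """Spearman rank correlation of CPM with ordinal cancer stage.

    Usable samples are HR (coded 0) and PDAC stages I-IV (coded 1-4 with
    substages merged); stage-0 and general-population samples are excluded.
    Constant miRNAs get rho = 0, p = 1 and a ``degenerate`` flag.
    """
    coding = DEFAULT_STAGE_CODING if stage_coding is None else stage_coding
    meta = meta.loc[cpm.columns]
    pdac_stages = [s for s in coding if s != "none"]
    usable = (meta["cohort"] == "HR") | (
        (meta["cohort"] == "PDAC") & meta["stage"].isin(pdac_stages))
    sub = meta.loc[usable]
    codes = sub["stage"].map(coding).to_numpy(dtype=float)
    if len(codes) < 3:
        raise ValueError("need at least 3 usable samples for the trend test")
    values = cpm.loc[:, sub.index]

    rows = []
    for mirna, v in values.iterrows():
        v = v.to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(codes) == 0:
            rows.append((mirna, 0.0, 1.0, True))
            continue
        rho, p = stats.spearmanr(v, codes)
        rows.append((mirna, float(rho), float(p), False))
    res = pd.DataFrame(rows, columns=["mirna", "spearman_rho", "p_value",
                                      "degenerate"]).set_index("mirna")
    res.attrs["stage_coding"] = dict(coding)
    return res
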