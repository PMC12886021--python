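"""Diagnostic evaluation: ROC/AUC, confusion metrics with confidence
intervals, stage-stratified sensitivity, PPV/NPV under an assumed
prevalence, CA19-9 comparison, and subgroup-bias association tests.

Interval conventions: hold-out proportions get Wilson score intervals
(Clopper-Pearson available as a secondary method for the small stage
strata); cross-validation fold metrics get the t interval
``mean +/- t_{k-1} * sd / sqrt(k)``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

EARLY_STAGES = ("0", "IA", "IB", "IIA")   # localized, resectable
LATE_STAGES = ("IIB", "III", "IV")        # unresectable

CA19_9_CUTOFF = 37.0  # U/mL, established clinical threshold


def roc_auc(labels, scores) -> float:
    """AUC = Mann-Whitney U / (n_pos * n_neg); ties count one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_at_threshold(labels, scores, threshold: float):
    """Sensitivity/specificity with the rule 'score >= threshold is positive'.

    Returns ``(sensitivity, specificity, counts)`` with raw
    TP/FP/TN/FN counts.
    """
    labels = np.asarray(labels)
    calls = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    fp = int(np.sum(calls & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec, {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def wilson_ci(successes: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # the k=0 / k=n bounds are exactly 0 / 1; clear rounding noise
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return lo, hi


def clopper_pearson_ci(successes: int, n: int, level: float = 0.95):
    """Exact (Clopper-Pearson) binomial interval, used as a secondary method
    for small stage strata."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def t_mean_ci(fold_values, level: float = 0.95):
    """``mean +/- t_{k-1} * sd / sqrt(k)`` over cross-validation folds.

    Returns ``(mean, sd, lower, upper)`` with the sample (n-1) SD.
    """
    v = np.asarray(fold_values, dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError("need at least 2 fold values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = stats.t.ppf(1 - (1 - level) / 2, df=k - 1) * sd / math.sqrt(k)
    return mean, sd, mean - half, mean + half


def ppv_npv(sensitivity: float, specificity: float, prevalence: float):
    """Positive/negative predictive value at an assumed disease prevalence.

    ``ppv = pi*s / (pi*s + (1-pi)*(1-c))``;
    ``npv = (1-pi)*c / ((1-pi)*c + pi*(1-s))``.
    A zero denominator yields ``nan`` for that value.
    """
    for name, v in (("sensitivity", sensitivity),
                    ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    s, c, pi = sensitivity, specificity, prevalence
    ppv_den = pi * s + (1 - pi) * (1 - c)
    npv_den = (1 - pi) * c + pi * (1 - s)
    ppv = pi * s / ppv_den if ppv_den > 0 else float("nan")
    npv = (1 - pi) * c / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


def stage_stratified_sensitivity(meta: pd.DataFrame, scores: pd.Series,
                                 threshold: float) -> dict:
    """Sensitivity among PDAC samples by stage group and by single stage.

    Early = stages 0-IIA (localized/resectable), late = IIB-IV.  Each group
    carries Wilson and Clopper-Pearson intervals; empty groups are reported
    as missing.
    """
    pdac = meta[meta["cohort"] == "PDAC"]
    out: dict[str, dict] = {}

    def group(name, stages):
        ids = pdac.index[pdac["stage"].isin(stages)]
        if len(ids) == 0:
            out[name] = {"n": 0, "sensitivity": None}
            return
        calls = scores.loc[ids] >= threshold
        hit = int(calls.sum())
        out[name] = {
            "n": int(len(ids)),
            "n_detected": hit,
            "sensitivity": hit / len(ids),
            "wilson_ci": wilson_ci(hit, len(ids)),
            "clopper_pearson_ci": clopper_pearson_ci(hit, len(ids)),
        }

    group("early", EARLY_STAGES)
    group("late", LATE_STAGES)
    for st in sorted(pdac["stage"].unique()):
        group(f"stage_{st}", (st,))
    return out


def ca199_classify(values, labels, cutoff: float = CA19_9_CUTOFF):
    """Sensitivity/specificity of the CA19-9 rule 'value > cutoff is positive'.

    Missing (NaN) measurements are excluded; the comparison is strict
    ('exceeding').  Returns ``(sensitivity, specificity, n_used)``.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(v)
    if np.any(v[ok] < 0):
        raise ValueError("CA19-9 concentrations must be non-negative")
    v, labels = v[ok], labels[ok]
    positive = v > cutoff
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    sens = float(np.sum(positive & (labels == 1)) / n_pos) if n_pos else float("nan")
    spec = float(np.sum(~positive & (labels == 0)) / n_neg) if n_neg else float("nan")
    return sens, spec, int(ok.sum())


def subgroup_association(scores, covariate) -> dict:
    """Association between prediction scores and a covariate.

    Continuous covariates get Pearson and Spearman correlations; binary ones
    a Wilcoxon rank-sum test; >= 3 categories a Kruskal-Wallis test.  Missing
    covariate values are dropped pairwise.  Returns a dict with the
    statistic, p-value and method tag.
    """
    s = pd.Series(scores).reset_index(drop=True)
    c = pd.Series(covariate).reset_index(drop=True)
    ok = s.notna() & c.notna()
    s, c = s[ok], c[ok]
    if len(s) < 3:
        raise ValueError("need at least 3 non-missing pairs")
    if c.nunique() == 1:
        return {"method": "constant", "statistic": float("nan"), "p": 1.0,
                "n": int(len(s)), "flagged": True}
    if pd.api.types.is_numeric_dtype(c) and c.nunique() > 6:
        pr, pp = stats.pearsonr(s, c.astype(float))
        sr, sp = stats.spearmanr(s, c.astype(float))
        return {"method": "correlation", "pearson_r": float(pr),
                "pearson_p": float(pp), "spearman_rho": float(sr),
                "spearman_p": float(sp), "statistic": float(pr),
                "p": float(pp), "n": int(len(s))}
    levels = sorted(c.unique(), key=str)
    groups = [s[c == lv].to_numpy() for lv in levels]
    if len(levels) == 2:
        stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided")
        return {"method": "rank_sum", "statistic": float(stat),
                "p": float(p), "n": int(len(s))}
    stat, p = stats.kruskal(*groups)
    return {"method": "kruskal_wallis", "statistic": float(stat),
            "p": float(p), "n": int(len(s))}
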