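"""Prevalence filtering and counts-per-million normalization.

Two regimes share these steps with different prevalence cutoffs: the
differential-expression stage keeps miRNAs with >= 2 counts in more than 50%
of samples (and passes raw counts to the NB test), while the machine-learning
stage uses the stricter 80% cutoff and feeds CPM values to the model.
Per-sample totals are always the column sums of the matrix as quantified
(after sample QC, before any row filtering).
"""

from __future__ import annotations

import pandas as pd


def prevalence_filter(counts: pd.DataFrame, min_count: int = 2,
                      min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep miRNAs detected (>= ``min_count``) in more than ``min_fraction``
    of samples; the 'more than' comparison is strict."""
    if counts.empty:
        raise ValueError("count matrix is empty")
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    n_detected = (counts >= min_count).sum(axis=1)
    keep = n_detected > min_fraction * counts.shape[1]
    return counts.loc[keep]


def cpm_normalize(counts: pd.DataFrame,
                  totals: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: scale each sample so its counts sum to 10^6.

    ``totals`` overrides the per-sample denominators — used when CPM should
    reflect totals over all quantified miRNAs even after row filtering.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = totals.loc[counts.columns]
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero))}")
    return counts / totals * 1e6
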