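"""Performance metrics for proportion estimates against known truth.

Per cell type the primary metric is the Pearson correlation between
estimated and true fractions across samples.  A single global summary,
the *correlation deviation*, is the RMS distance of the per-type
correlations from 1:

    sqrt( (1/n) * sum_i (1 - r_i)^2 )

It is 0 exactly when every cell type is estimated with r = 1 and grows
with both the number and severity of poorly estimated types.  A
threshold-free ranking metric, AUC at the median-truth cutoff, binarizes
the true fractions at their median and asks how well the estimates
separate high- from low-infiltration samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

logger = logging.getLogger(__name__)

__all__ = ["pearson_by_type", "correlation_deviation", "auc_median_cutoff", "metric_report"]


def pearson_by_type(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """Pearson r per cell type over samples present in both tables.

    Both inputs are tidy tables with columns (sample_id, cell_type, value);
    the estimate value column may be named ``estimated_proportion`` or
    ``fraction``.  Types with fewer than 3 paired samples or zero variance
    in either vector get NaN with a warning.
    """
    est = estimates.rename(columns={"estimated_proportion": "value"})
    tru = truth.rename(columns={"fraction": "value_true"})
    merged = est.merge(tru, on=["sample_id", "cell_type"], how="inner")
    out = {}
    for ct, grp in merged.groupby("cell_type"):
        x = grp["value"].to_numpy(dtype=float)
        y = grp["value_true"].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if len(x) < 3:
            logger.warning("%s: fewer than 3 paired samples; r undefined", ct)
            out[ct] = np.nan
        elif np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("%s: zero variance; r undefined", ct)
            out[ct] = np.nan
        else:
            out[ct] = float(pearsonr(x, y).statistic)
    return pd.Series(out, name="pearson_r")


def correlation_deviation(r_list, *, root: bool = True) -> float:
    """RMS deviation of per-type correlations from perfect agreement.

    NaN entries (undefined correlations) are excluded with a logged count.
    ``root=False`` gives the plain mean-square variant for comparison.
    """
    r = np.asarray(list(r_list), dtype=float)
    bad = np.isnan(r)
    if bad.any():
        logger.warning("excluding %d undefined correlations", int(bad.sum()))
        r = r[~bad]
    if r.size == 0:
        raise ValueError("no defined correlations to summarize")
    ms = float(np.mean((1.0 - r) ** 2))
    return float(np.sqrt(ms)) if root else ms


def auc_median_cutoff(estimates, truth) -> float:
    """AUC for recovering above-median true infiltration from estimates.

    The true fractions are binarized at their median (strictly greater =
    positive; samples exactly at the median count as negative).  The AUC
    is the rank-based probability that a random positive sample's estimate
    exceeds a random negative's, ties counted 1/2 — equivalent to the
    Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if len(est) != len(tru):
        raise ValueError("estimates and truth must be the same length")
    if len(est) < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(tru) == 0:
        raise ValueError("true fractions are constant; cutoff undefined")
    positive = tru > np.median(tru)
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning("one class empty after median binarization; AUC undefined")
        return float("nan")
    ranks = rankdata(est)  # average ranks handle ties as 1/2 wins
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def metric_report(estimates: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Bundle per-type Pearson r, AUCs and the global correlation deviation."""
    r = pearson_by_type(estimates, truth)
    est = estimates.rename(columns={"estimated_proportion": "value"})
    merged = est.merge(
        truth.rename(columns={"fraction": "value_true"}),
        on=["sample_id", "cell_type"],
    )
    aucs = {}
    for ct, grp in merged.groupby("cell_type"):
        try:
            aucs[ct] = auc_median_cutoff(grp["value"], grp["value_true"])
        except ValueError:
            aucs[ct] = float("nan")
    return {
        "pearson_r": {ct: (None if np.isnan(v) else float(v)) for ct, v in r.items()},
        "n_samples": {
            ct: int(len(grp)) for ct, grp in merged.groupby("cell_type")
        },
        "correlation_deviation": correlation_deviation(r.dropna()),
        "auc_median_cutoff": {
            ct: (None if np.isnan(v) else float(v)) for ct, v in aucs.items()
        },
    }
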