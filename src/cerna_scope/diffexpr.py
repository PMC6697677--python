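"""Differential-expression calling for small two-group microarray designs.

The selection rule is the classic microarray one: a feature is dysregulated
when its linear fold change (case mean / control mean) is >= 1.5 (or <= 1/1.5)
AND a two-sided Mann-Whitney U test gives p <= 0.05.  At the n = 4 vs 4 design
this study size implies, the U null distribution is tiny (70 group
assignments), so the test is computed by exact enumeration; the smallest
attainable two-sided p is 2/70 ~ 0.0286, i.e. a call requires (near-)complete
separation of the groups.  Benjamini-Hochberg FDR is reported for every
feature but is not part of the selection rule.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

#: largest total sample count for which the exact enumeration test is used
EXACT_ENUMERATION_LIMIT = 12

DE_COLUMNS = ["feature_id", "fold_change", "p_value", "fdr", "direction"]


# --------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize the sample columns of an expression matrix.

    Every column is forced onto the common reference distribution given by
    the mean of the per-rank sorted values across samples; feature order is
    preserved.  Tied values receive the mean of the reference values their
    tied ranks span.  A single-sample matrix is returned unchanged with a
    warning.
    """
    values = matrix.values.to_numpy(dtype=float)
    n_feat, n_samp = values.shape
    if n_samp < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return matrix
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n_feat + 1, dtype=float)
    for j in range(n_samp):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(frame)


# --------------------------------------------------------------------------
# exact Mann-Whitney machinery


def _combo_masks(n_total: int, n_case: int) -> np.ndarray:
    """Boolean matrix (C(n_total, n_case) x n_total): all case assignments."""
    combos = list(itertools.combinations(range(n_total), n_case))
    masks = np.zeros((len(combos), n_total), dtype=float)
    for i, idx in enumerate(combos):
        masks[i, list(idx)] = 1.0
    return masks


def exact_mannwhitney_pvalues(values: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided Mann-Whitney p per row of ``values``.

    For each feature (row) the midrank sum of the case columns is compared
    with its permutation distribution over all C(n, n_case) group
    assignments; p is the doubled smaller tail probability, capped at 1
    (equal-tail convention for the discrete statistic).  Ties are handled by
    enumerating midrank statistics.
    """
    values = np.asarray(values, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    n_total = values.shape[1]
    masks = _combo_masks(n_total, int(case_mask.sum()))
    ranks = stats.rankdata(values, method="average", axis=1)
    # midranks are multiples of 0.5, so rank sums are exact in float64
    w_all = ranks @ masks.T  # (features, n_combos)
    w_obs = ranks[:, case_mask].sum(axis=1, keepdims=True)
    eps = 1e-9
    p_le = (w_all <= w_obs + eps).mean(axis=1)
    p_ge = (w_all >= w_obs - eps).mean(axis=1)
    return np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))


def mann_whitney_exact(case_values, control_values) -> float:
    """Two-sided Mann-Whitney U p-value for one feature.

    Exact by enumeration of all C(n1+n2, n1) group assignments when
    n1 + n2 <= 12; normal approximation with midranks and tie correction
    otherwise.  A completely tied input gives p = 1 (no evidence), not an
    error.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("each group needs at least 2 values")
    n_total = case.size + control.size
    if n_total <= EXACT_ENUMERATION_LIMIT:
        row = np.concatenate([case, control])[None, :]
        mask = np.zeros(n_total, dtype=bool)
        mask[: case.size] = True
        return float(exact_mannwhitney_pvalues(row, mask)[0])
    if np.ptp(np.concatenate([case, control])) == 0:
        return 1.0
    return float(
        stats.mannwhitneyu(case, control, alternative="two-sided", method="asymptotic").pvalue
    )


def exact_null_pvalue_distribution(n_case: int, n_control: int) -> pd.Series:
    """Null pmf over the attainable exact p-values for untied data.

    Returns a Series indexed by attainable p (ascending) whose values are the
    null probabilities P(p-value = p).  Useful for goodness-of-fit checks of
    null calibration at small n.
    """
    n_total = n_case + n_control
    row = np.arange(1, n_total + 1, dtype=float)[None, :]
    masks = _combo_masks(n_total, n_case).astype(bool)
    pvals = [float(exact_mannwhitney_pvalues(row, m)[0]) for m in masks]
    counts = pd.Series(pvals).value_counts().sort_index()
    return counts / comb(n_total, n_case)


# --------------------------------------------------------------------------
# DE calling


def call_de(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    log_scale_fc: bool = False,
) -> pd.DataFrame:
    """Call differential expression for every feature of a matrix.

    Returns a DataFrame with columns ``feature_id, fold_change, p_value,
    fdr, direction`` where direction is ``up`` iff fold_change >=
    ``fc_threshold`` and p <= ``p_threshold``, ``down`` iff fold_change <=
    1/``fc_threshold`` and p <= ``p_threshold``, else ``none``.  Fold change
    is the ratio of arithmetic group means on the linear normalized scale
    (geometric means of the intensities when ``log_scale_fc``).  BH FDR is
    computed over all callable features and reported but never used for
    selection.  Features with a nonpositive group mean are flagged
    (``direction='none'``, NaN statistics) and logged rather than imputed.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    case = matrix.case_values()
    control = matrix.control_values()
    if log_scale_fc:
        case_mean = 2.0 ** np.log2(case).mean(axis=1)
        control_mean = 2.0 ** np.log2(control).mean(axis=1)
    else:
        case_mean = case.mean(axis=1)
        control_mean = control.mean(axis=1)
    ok = (control_mean > 0) & (case_mean > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("call_de: %d features with nonpositive group mean excluded", n_bad)

    fc = np.full(case_mean.shape, np.nan)
    fc[ok] = case_mean[ok] / control_mean[ok]

    values = np.concatenate([case, control], axis=1)
    case_mask = np.zeros(values.shape[1], dtype=bool)
    case_mask[: case.shape[1]] = True
    pvals = np.full(case_mean.shape, np.nan)
    if values.shape[1] <= EXACT_ENUMERATION_LIMIT:
        pvals[ok] = exact_mannwhitney_pvalues(values[ok], case_mask)
    else:
        res = stats.mannwhitneyu(
            case[ok], control[ok], alternative="two-sided", method="asymptotic", axis=1
        )
        pvals[ok] = res.pvalue

    fdr = np.full(case_mean.shape, np.nan)
    if ok.any():
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]

    direction = np.full(case_mean.shape, "none", dtype=object)
    sig = ok & (pvals <= p_threshold)
    direction[sig & (fc >= fc_threshold)] = "up"
    direction[sig & (fc <= 1.0 / fc_threshold)] = "down"

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids.to_numpy(),
            "fold_change": fc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )


def dysregulated_ids(de_table: pd.DataFrame, direction: str | None = None) -> set[str]:
    """Feature ids called dysregulated (optionally in one direction)."""
    if direction is None:
        mask = de_table["direction"] != "none"
    else:
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        mask = de_table["direction"] == direction
    return set(de_table.loc[mask, "feature_id"])


# --------------------------------------------------------------------------
# time specificity


@dataclasses.dataclass(frozen=True)
class TimeSpecificitySummary:
    """Accounting of dysregulation overlap between two time points.

    ``n_distinct`` counts distinct dysregulated features across both times,
    ``n_specific`` those dysregulated at exactly one, and
    ``fraction_specific`` is 100 * n_specific / n_distinct.
    """

    n_time1: int
    n_time2: int
    n_both: int
    n_distinct: int
    n_specific: int
    fraction_specific: float

    @classmethod
    def from_counts(cls, n_time1: int, n_time2: int, n_both: int) -> "TimeSpecificitySummary":
        if n_both > min(n_time1, n_time2):
            raise ValueError("overlap exceeds a per-time count")
        n_distinct = n_time1 + n_time2 - n_both
        n_specific = n_distinct - n_both
        frac = 100.0 * n_specific / n_distinct if n_distinct else 0.0
        return cls(n_time1, n_time2, n_both, n_distinct, n_specific, frac)


def time_specificity(de_time1: pd.DataFrame, de_time2: pd.DataFrame) -> TimeSpecificitySummary:
    """Summarize how time-specific dysregulation is across two DE tables.

    Both tables must cover the same feature universe; a feature counts as
    dysregulated at a time point when its direction there is not ``none``.
    """
    u1 = set(de_time1["feature_id"])
    u2 = set(de_time2["feature_id"])
    if u1 != u2:
        only1, only2 = sorted(u1 - u2)[:5], sorted(u2 - u1)[:5]
        raise ValueError(
            f"feature universes differ: {len(u1 - u2)} only at time 1 (e.g. {only1}), "
            f"{len(u2 - u1)} only at time 2 (e.g. {only2})"
        )
    d1 = dysregulated_ids(de_time1)
    d2 = dysregulated_ids(de_time2)
    return TimeSpecificitySummary.from_counts(len(d1), len(d2), len(d1 & d2))
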