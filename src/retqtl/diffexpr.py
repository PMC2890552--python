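"""Strain/age comparisons with SAM-style permutation FDR.

Four contrasts are computed from the dye-corrected, oriented log2(C/B6a)
matrix:

* ``all16`` — is the average adjusted C/B6a ratio over all chips non-zero
  (one-group t test);
* ``m4`` / ``m8`` — the same restricted to the 4-month or 8-month chips;
* ``age_dependency`` — does the strain difference change with age
  (two-sample Welch t, 8-month minus 4-month chip values per gene).

The false discovery rate follows the Significance Analysis of Microarrays
permutation scheme: null t statistics come from random sign flips of the
chip columns (one-group contrasts) or random age-label shuffles
(age dependency); for a threshold c,
``q(c) = median over permutations of #{null |t| >= c} / #{observed |t| >= c}``,
monotonized so q never increases with |t| and capped at 1. Genes are called
regulated when (FC >= 1.2 or FC <= 0.8) and q < 0.05, boundaries inclusive
on the fold-change side as written.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import RatioMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARISONS",
    "one_group_t",
    "two_sample_t",
    "run_comparisons",
    "permutation_fdr",
    "call_regulated",
]

COMPARISONS = ("all16", "m4", "m8", "age_dependency")

Comparison = Literal["all16", "m4", "m8", "age_dependency"]


def one_group_t(values: np.ndarray) -> tuple[float, float, float]:
    """Mean, t and two-sided p for H0: mean = 0 (one-group t test).

    ``t = mean / (sd / sqrt(n))`` with sd the n-1 sample SD; p from the t
    distribution with n-1 degrees of freedom. Requires n >= 3 non-missing
    values. A zero-SD (constant) gene has no defined t: (mean, nan, nan)
    is returned and a warning logged; such genes are excluded from FDR
    ranking.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 3:
        raise ValueError(f"one-group t needs >= 3 non-missing values, got {n}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        logger.warning("degenerate gene: zero SD over %d values", n)
        return mean, float("nan"), float("nan")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return mean, float(t), p


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t for H0: mean(a) = mean(b); returns (mean(a)-mean(b), t, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("two-sample t needs >= 3 values per group")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        logger.warning("degenerate gene: zero SD in both age groups")
        return diff, float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(t), float(p)


def _comparison_chips(matrix: RatioMatrix, comparison: Comparison) -> list[str]:
    if comparison == "all16":
        return list(matrix.values.columns)
    if comparison == "m4":
        return matrix.chips_with(age_months=4)
    if comparison == "m8":
        return matrix.chips_with(age_months=8)
    raise ValueError(comparison)


def _stats_for_subset(values: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for gene, row in values.iterrows():
        v = row.to_numpy(float)
        if np.sum(~np.isnan(v)) < 3:
            continue  # too few values for this contrast
        rows[gene] = one_group_t(v)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_log2_C_over_B6a", "t_stat", "p_value"])


def run_comparisons(matrix: RatioMatrix, n_perm: int = 1000,
                    seed: int | None = 0) -> dict[str, pd.DataFrame]:
    """All four contrasts with permutation FDR; one DataFrame per comparison.

    Columns: mean_log2_C_over_B6a, FC, t_stat, p_value, q_value. For
    comparisons 1-3, FC = 2**mean; for age dependency the mean is the
    8-month minus 4-month difference of log ratios and FC is its linear
    equivalent.
    """
    if matrix.stage != "dye_corrected_oriented":
        raise ValueError("comparisons require the dye-corrected, oriented matrix")
    results: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed)
    for comparison in ("all16", "m4", "m8"):
        sub = matrix.values[_comparison_chips(matrix, comparison)]
        res = _stats_for_subset(sub)
        res["FC"] = 2.0 ** res["mean_log2_C_over_B6a"]
        res["q_value"] = permutation_fdr(
            res["t_stat"], sub, "one_group", n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)))
        results[comparison] = res

    chips4 = matrix.chips_with(age_months=4)
    chips8 = matrix.chips_with(age_months=8)
    rows = {}
    for gene in matrix.values.index:
        a = matrix.values.loc[gene, chips8].to_numpy(float)
        b = matrix.values.loc[gene, chips4].to_numpy(float)
        if np.sum(~np.isnan(a)) < 3 or np.sum(~np.isnan(b)) < 3:
            continue
        rows[gene] = two_sample_t(a, b)
    res4 = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_log2_C_over_B6a", "t_stat", "p_value"])
    res4["FC"] = 2.0 ** res4["mean_log2_C_over_B6a"]
    res4["q_value"] = permutation_fdr(
        res4["t_stat"], matrix.values[chips4 + chips8], "two_sample",
        n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        group_sizes=(len(chips4), len(chips8)))
    results["age_dependency"] = res4
    return results


def _one_group_t_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise one-group t over a genes x chips array with NaNs; vectorized."""
    n = np.sum(~np.isnan(values), axis=1)
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) | (n < 3)] = np.nan
    return t


def _two_sample_t_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t between two genes x chips arrays with NaNs."""
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        va = np.nanvar(a, axis=1, ddof=1) / na
        vb = np.nanvar(b, axis=1, ddof=1) / nb
        t = (np.nanmean(a, axis=1) - np.nanmean(b, axis=1)) / np.sqrt(va + vb)
    t[(na < 3) | (nb < 3)] = np.nan
    return t


def permutation_fdr(observed_t: pd.Series, values: pd.DataFrame,
                    kind: Literal["one_group", "two_sample"],
                    n_perm: int = 1000, seed: int | None = 0,
                    group_sizes: tuple[int, int] | None = None) -> pd.Series:
    """SAM-style q value per gene from a permutation null.

    One-group contrasts: each permutation draws a random +/-1 sign per chip
    column, applied to all genes (preserving gene-gene correlation).
    Two-sample contrast: each permutation shuffles the age labels of the
    chip columns. For each observed threshold c = |t_gene|,
    q = median_perm #{null |t| >= c} / #{observed |t| >= c}, then q is made
    non-increasing in |t| and capped at 1.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    arr = values.reindex(observed_t.index).to_numpy(float)
    n_chips = arr.shape[1]

    obs = np.abs(observed_t.to_numpy(float))
    defined = ~np.isnan(obs)
    obs_def = obs[defined]
    order = np.argsort(-obs_def)  # descending |t|
    sorted_obs = obs_def[order]
    n_obs_ge = np.arange(1, sorted_obs.size + 1)  # #{observed |t| >= c}

    null_counts = np.empty((n_perm, sorted_obs.size))
    for i in range(n_perm):
        if kind == "one_group":
            signs = rng.choice([-1.0, 1.0], size=n_chips)
            t_null = _one_group_t_matrix(arr * signs)
        else:
            if group_sizes is None:
                raise ValueError("group_sizes required for two-sample permutation")
            perm = rng.permutation(n_chips)
            ga = arr[:, perm[: group_sizes[0]]]
            gb = arr[:, perm[group_sizes[0]:]]
            t_null = _two_sample_t_matrix(gb, ga)
        t_null = np.abs(t_null[~np.isnan(t_null)])
        t_null.sort()
        # #{null |t| >= c} for each observed threshold c
        null_counts[i] = t_null.size - np.searchsorted(t_null, sorted_obs,
                                                       side="left")

    med_null = np.median(null_counts, axis=0)
    q_sorted = med_null / n_obs_ge
    # monotone: q non-increasing as |t| increases == running min from the top
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)

    q = np.full(obs.shape, np.nan)
    q_def = np.empty(obs_def.shape)
    q_def[order] = q_sorted
    q[defined] = q_def
    return pd.Series(q, index=observed_t.index, name="q_value")


def call_regulated(fc, q, fc_up: float = 1.2, fc_down: float = 0.8,
                   fdr: float = 0.05):
    """Regulated-gene call: (FC >= fc_up or FC <= fc_down) and q < fdr.

    The fold-change boundaries are inclusive as written; the FDR bound is
    strict. Works elementwise on arrays/Series or on scalars.
    """
    fc_arr = np.asarray(fc, float)
    q_arr = np.asarray(q, float)
    out = ((fc_arr >= fc_up) | (fc_arr <= fc_down)) & (q_arr < fdr)
    if np.isscalar(fc) or fc_arr.ndim == 0:
        return bool(out)
    if isinstance(fc, pd.Series):
        return pd.Series(out, index=fc.index, name="regulated")
    return out
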