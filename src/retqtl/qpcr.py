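"""Comparative-Ct relative expression and ANOVA with Holm-Sidak comparisons.

Relative expression follows ``y = (1 + AE)**ddCt`` with the amplification
efficiency AE fixed at 1.0 (perfect doubling) unless stated otherwise.
``dCt`` is the target Ct minus the beta-actin reference Ct; technical
triplicates are averaged to one Ct per biological replicate (pooled sample)
before any statistics. Folds are reported relative to a calibrator group
(B6a at four months by convention), whose fold is exactly 1. The sign is the
standard Livak orientation: ddCt = dCt(calibrator) - dCt(group), so a more
abundant target (lower dCt) gives fold > 1.

Group comparison is a one-way ANOVA followed by Holm-Sidak stepdown
pairwise tests: order the m raw pairwise p values ascending and set
``p_adj(k) = max_{j<=k} [1 - (1 - p(j))**(m - j + 1)]``, clipped to 1.
The ANOVA/pairwise tests run on the dCt scale by default (where normality
is more plausible than on folds); ``on="fold"`` switches scales.
"""

from __future__ import annotations

import itertools
import logging
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "delta_ct",
    "relative_expression",
    "holm_sidak",
    "anova_holm_sidak",
    "compare_groups",
    "CALIBRATOR",
]

CALIBRATOR = ("B6a", 4)


def delta_ct(measurements: pd.DataFrame) -> pd.DataFrame:
    """One dCt per biological replicate per group.

    Expects the Ct-table layout (columns gene, strain, age, replicate, well,
    ct_target, ct_reference); technical wells are averaged within replicate
    first, separately for target and reference. Replicates lacking a
    reference Ct are dropped with a warning.
    """
    df = measurements.copy()
    n_before = df[["strain", "age", "replicate"]].drop_duplicates().shape[0]
    df = df.dropna(subset=["ct_reference", "ct_target"])
    per_rep = (
        df.groupby(["strain", "age", "replicate"], sort=True)[
            ["ct_target", "ct_reference"]
        ]
        .mean()
        .reset_index()
    )
    if per_rep.shape[0] < n_before:
        logger.warning("dropped %d replicate(s) with missing Ct values",
                       n_before - per_rep.shape[0])
    per_rep["delta_ct"] = per_rep["ct_target"] - per_rep["ct_reference"]
    return per_rep


def relative_expression(measurements: pd.DataFrame, ae: float = 1.0,
                        calibrator: tuple[str, int] = CALIBRATOR) -> pd.DataFrame:
    """Fold change per strain x age group relative to the calibrator.

    ``fold = (1 + AE) ** (dCt_calibrator - dCt_group)`` using group-mean
    dCt values. The calibrator's fold is exactly 1 by construction.
    """
    per_rep = delta_ct(measurements)
    group_dct = per_rep.groupby(["strain", "age"])["delta_ct"].mean()
    if calibrator not in group_dct.index:
        raise ValueError(f"calibrator group {calibrator} absent from data")
    dct_cal = group_dct.loc[calibrator]
    fold = (1.0 + ae) ** (dct_cal - group_dct)
    out = fold.rename("fold").reset_index()
    out["calibrator"] = [calibrator] * len(out)
    return out


def holm_sidak(p_raw: Sequence[float]) -> np.ndarray:
    """Holm-Sidak stepdown adjustment of a vector of raw p values.

    Adjusted values are monotone in the raw ordering and never below the
    raw p; order of the output matches the input order.
    """
    p = np.asarray(p_raw, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)  # stepdown monotonization
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def anova_holm_sidak(values_by_group: Mapping[Hashable, Sequence[float]]
                     ) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA p plus the Holm-Sidak-adjusted pairwise p matrix.

    Pairwise comparisons are two-sample t tests between every pair of
    groups, adjusted jointly by the Holm-Sidak stepdown. Requires >= 2
    groups with >= 2 values each; all-degenerate (zero-variance) input is
    an error.
    """
    groups = {k: np.asarray(v, float)[~np.isnan(np.asarray(v, float))]
              for k, v in values_by_group.items()}
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(v.std(ddof=1) == 0 for v in groups.values()):
        raise ValueError("zero within-group variance in all groups")
    keys = list(groups)
    _, anova_p = stats.f_oneway(*groups.values())
    pairs = list(itertools.combinations(keys, 2))
    raw = []
    for a, b in pairs:
        if groups[a].std(ddof=1) == 0 and groups[b].std(ddof=1) == 0:
            raw.append(0.0 if groups[a].mean() != groups[b].mean() else 1.0)
        else:
            raw.append(float(stats.ttest_ind(groups[a], groups[b]).pvalue))
    adj = holm_sidak(raw)
    arr = np.full((len(keys), len(keys)), np.nan)
    pos = {k: i for i, k in enumerate(keys)}
    for (a, b), p in zip(pairs, adj):
        arr[pos[a], pos[b]] = arr[pos[b], pos[a]] = p
    mat = pd.DataFrame(arr, index=keys, columns=keys)
    return float(anova_p), mat


def compare_groups(measurements: pd.DataFrame,
                   on: str = "delta_ct") -> tuple[float, pd.DataFrame]:
    """ANOVA + Holm-Sidak across strain x age groups of a Ct table.

    ``on="delta_ct"`` (default) tests reference-normalized Ct values;
    ``on="fold"`` tests per-replicate folds instead.
    """
    per_rep = delta_ct(measurements)
    if on == "fold":
        cal = per_rep.groupby(["strain", "age"])["delta_ct"].mean().loc[CALIBRATOR]
        per_rep = per_rep.assign(value=2.0 ** (cal - per_rep["delta_ct"]))
    elif on == "delta_ct":
        per_rep = per_rep.assign(value=per_rep["delta_ct"])
    else:
        raise ValueError(f"unknown scale {on!r}")
    grouped = {
        f"{s}_{int(a)}m": g["value"].to_numpy()
        for (s, a), g in per_rep.groupby(["strain", "age"])
    }
    return anova_holm_sidak(grouped)
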