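"""Dye-swap normalization chain for two-color spotted arrays.

The chain reproduces the study's processing order exactly:

1. per-chip M/A computation, ``M = log2(ch2/ch1)``, ``A = log2(sqrt(ch1*ch2))``;
2. per-chip Lowess correction of the intensity-dependent dye bias
   (tricube-weighted local linear fit, fraction ``f`` of the data, evaluated
   at the observed A values);
3. linear rescaling so every chip's log-ratio SD equals the median SD
   across chips;
4. estimation of the per-gene dye effect D from the balanced dye swap —
   with C-on-Cy5 chips measuring ``s + D`` and B6a-on-Cy5 chips measuring
   ``-s + D`` (s the strain effect), the two orientation means sum to 2D —
   and its removal with orientation flipping so every chip estimates
   ``log2(C/B6a)``;
5. exclusion of genes missing half or more of the values in either
   orientation.

Values are NaN where missing; the missingness mask only ever grows.
Normalization runs at probe level; probes are collapsed to genes by the
per-chip median before the missing-value filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_formats import ChipDesign, Orientation, TwoColorChip

logger = logging.getLogger(__name__)

__all__ = [
    "RatioMatrix",
    "compute_log_ratios",
    "lowess_correct",
    "build_ratio_matrix",
    "collapse_probes_to_genes",
    "rescale_chips",
    "estimate_dye_effect",
    "remove_dye_and_orient",
    "filter_missing",
    "normalize_pipeline",
]

STAGES = ("raw", "lowess", "rescaled", "dye_corrected_oriented")


@dataclass
class RatioMatrix:
    """Genes (or probes) x chips matrix of log2 ratios plus the chip design.

    After stage ``dye_corrected_oriented`` every value estimates
    ``log2(C/B6a)`` regardless of the chip's dye orientation.
    """

    values: pd.DataFrame  # rows: probe/gene ids, columns: chip ids; NaN = missing
    design: ChipDesign
    stage: str = "raw"
    level: str = "probe"  # "probe" or "gene"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing_chips = set(self.values.columns) - set(self.design.chip_ids)
        if missing_chips:
            raise ValueError(f"chips absent from design: {sorted(missing_chips)}")

    @property
    def n_non_missing(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def chips_with(self, **kw) -> list[str]:
        return [c for c in self.design.chips_with(**kw) if c in self.values.columns]


def compute_log_ratios(chip: TwoColorChip) -> pd.DataFrame:
    """Per-spot M and A for one chip, indexed by probe.

    M and A are defined where both channels are strictly positive and the
    spot is unflagged; otherwise NaN (missingness, not failure).
    """
    df = chip.to_frame().set_index("probe")
    ch1 = df["ch1"].to_numpy(float)
    ch2 = df["ch2"].to_numpy(float)
    ok = (ch1 > 0) & (ch2 > 0) & ~df["flag"].astype(bool).to_numpy()
    m = np.full(len(df), np.nan)
    a = np.full(len(df), np.nan)
    m[ok] = np.log2(ch2[ok] / ch1[ok])
    a[ok] = 0.5 * (np.log2(ch1[ok]) + np.log2(ch2[ok]))  # log2 sqrt(ch1*ch2)
    return pd.DataFrame({"M": m, "A": a, "gene": df["gene"]}, index=df.index)


def lowess_correct(m: np.ndarray, a: np.ndarray, span: float = 0.33,
                   iterations: int = 3) -> np.ndarray:
    """Subtract the Lowess trend of M on A: ``M' = M - g_hat(A)``.

    ``g_hat`` is a tricube-weighted local linear regression using fraction
    ``span`` of the data per window, with robustifying iterations, evaluated
    at the observed A values. Missing values pass through as NaN.
    """
    m = np.asarray(m, float)
    a = np.asarray(a, float)
    ok = ~(np.isnan(m) | np.isnan(a))
    n_ok = int(ok.sum())
    if n_ok < 10:
        raise ValueError(
            f"need >= 10 non-missing (M, A) pairs for lowess, got {n_ok}; "
            "supply more data or a larger span"
        )
    if max(2, int(math.ceil(span * n_ok))) < 2:
        raise ValueError("span window too small; increase span")
    fitted = _sm_lowess(m[ok], a[ok], frac=span, it=iterations,
                        return_sorted=False)
    out = np.full_like(m, np.nan)
    out[ok] = m[ok] - fitted
    return out


def build_ratio_matrix(chips: list[TwoColorChip], design: ChipDesign,
                       span: float = 0.33,
                       apply_lowess: bool = True) -> RatioMatrix:
    """Lowess-correct every chip and assemble the probe x chip log-ratio matrix.

    ``apply_lowess=False`` takes the raw M values instead (for data with no
    intensity-dependent bias, or pre-corrected exports); the matrix is still
    tagged 'lowess' since it enters the chain at that point.
    """
    columns = {}
    gene_of: pd.Series | None = None
    for chip in chips:
        ma = compute_log_ratios(chip)
        m = ma["M"].to_numpy()
        if apply_lowess:
            m = lowess_correct(m, ma["A"].to_numpy(), span=span)
        columns[chip.chip_id] = pd.Series(m, index=ma.index)
        if gene_of is None:
            gene_of = ma["gene"]
        elif not gene_of.equals(ma["gene"]):
            raise ValueError(f"chip {chip.chip_id}: probe/gene layout differs")
    values = pd.DataFrame(columns)
    mat = RatioMatrix(values, design, stage="lowess", level="probe")
    mat.values.attrs["gene_of"] = dict(gene_of) if gene_of is not None else {}
    return mat


def collapse_probes_to_genes(matrix: RatioMatrix,
                             gene_of: dict[str, str] | None = None) -> RatioMatrix:
    """Collapse probe rows to gene rows by the per-chip median of probe values.

    The median is robust to a single bad clone among a gene's probes.
    """
    if matrix.level != "probe":
        raise ValueError("matrix already at gene level")
    gene_of = gene_of or matrix.values.attrs.get("gene_of")
    if not gene_of:
        raise ValueError("no probe->gene map available")
    genes = pd.Series({p: gene_of[p] for p in matrix.values.index})
    collapsed = matrix.values.groupby(genes).median()
    out = RatioMatrix(collapsed, matrix.design, stage=matrix.stage, level="gene")
    return out


def rescale_chips(matrix: RatioMatrix) -> RatioMatrix:
    """Rescale each chip so its log-ratio SD equals the median SD across chips.

    SD is computed over non-missing values with denominator n - 1.
    """
    if matrix.stage != "lowess":
        raise ValueError(f"rescale expects stage 'lowess', got {matrix.stage!r}")
    sds = matrix.values.std(axis=0, ddof=1, skipna=True)
    if (sds == 0).any() or sds.isna().any():
        bad = list(sds.index[(sds == 0) | sds.isna()])
        raise ValueError(f"degenerate chip(s) with zero/undefined SD: {bad}")
    target = float(np.median(sds))
    scaled = matrix.values * (target / sds)
    return replace(matrix, values=scaled, stage="rescaled")


def estimate_dye_effect(matrix: RatioMatrix) -> pd.Series:
    """Per-gene dye effect D from the balanced dye swap.

    D = (mean over C-on-Cy5 chips + mean over B6a-on-Cy5 chips) / 2, each
    mean over non-missing values only. D is NaN for genes with all values
    missing in one orientation.
    """
    if matrix.stage != "rescaled":
        raise ValueError(f"dye effect expects stage 'rescaled', got {matrix.stage!r}")
    c_chips = matrix.chips_with(orientation=Orientation.C_ON_CY5)
    b_chips = matrix.chips_with(orientation=Orientation.B6A_ON_CY5)
    if not c_chips or not b_chips:
        raise ValueError("both dye orientations must be present")
    mean_c = matrix.values[c_chips].mean(axis=1, skipna=True)
    mean_b = matrix.values[b_chips].mean(axis=1, skipna=True)
    return (mean_c + mean_b) / 2.0


def remove_dye_and_orient(matrix: RatioMatrix, dye: pd.Series) -> RatioMatrix:
    """Remove the dye effect and flip so all chips estimate log2(C/B6a).

    C-on-Cy5 chips: ``v - D``; B6a-on-Cy5 chips: ``-v + D``.
    """
    if matrix.stage != "rescaled":
        raise ValueError(f"orientation flip expects stage 'rescaled', got {matrix.stage!r}")
    dye = dye.reindex(matrix.values.index)
    out = matrix.values.copy()
    for chip in out.columns:
        if matrix.design.orientation_of(chip) is Orientation.C_ON_CY5:
            out[chip] = out[chip] - dye
        else:
            out[chip] = -out[chip] + dye
    return replace(matrix, values=out, stage="dye_corrected_oriented")


def filter_missing(matrix: RatioMatrix,
                   max_missing: int | None = None) -> tuple[RatioMatrix, int]:
    """Drop genes missing too many values in either dye orientation.

    In the canonical 16-chip design a gene is excluded when 4 or more of the
    8 values in either orientation are missing. For other balanced designs
    the threshold generalizes to ``ceil(n_orientation_chips / 2)``.
    Returns the filtered matrix and the number of genes removed.
    """
    remove = pd.Series(False, index=matrix.values.index)
    for orient in Orientation:
        chips = matrix.chips_with(orientation=orient)
        thr = max_missing if max_missing is not None else math.ceil(len(chips) / 2)
        n_missing = matrix.values[chips].isna().sum(axis=1)
        remove |= n_missing >= thr
    n_removed = int(remove.sum())
    logger.info("missing-value filter removed %d of %d rows",
                n_removed, len(remove))
    return replace(matrix, values=matrix.values[~remove]), n_removed


def normalize_pipeline(chips: list[TwoColorChip], design: ChipDesign,
                       span: float = 0.33,
                       apply_lowess: bool = True) -> tuple[RatioMatrix, dict]:
    """Run the full chain; returns the final gene-level matrix and an audit dict."""
    probe_mat = build_ratio_matrix(chips, design, span=span,
                                   apply_lowess=apply_lowess)
    gene_mat = collapse_probes_to_genes(probe_mat)
    rescaled = rescale_chips(gene_mat)
    dye = estimate_dye_effect(rescaled)
    oriented = remove_dye_and_orient(rescaled, dye)
    filtered, n_removed = filter_missing(oriented)
    audit = {
        "n_probes": int(probe_mat.values.shape[0]),
        "n_genes": int(gene_mat.values.shape[0]),
        "n_genes_removed_missing": n_removed,
        "n_genes_final": int(filtered.values.shape[0]),
        "dye_effect": dye,
    }
    return filtered, audit
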