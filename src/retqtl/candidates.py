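"""QTL candidate-gene prioritization.

Three steps produce the ranked candidate table:

1. map genes to the refined QTL intervals (closed megabase intervals,
   any overlap counts; Chr 6: 77.5-93.0 Mb, Chr 10: 15.4-20.8 Mb in the
   original study);
2. keep genes with at least one SNP fitting the strain haplotype
   B6 != C and A != C (the candidate allele must differ between the
   contrasted strains and be absent from the strain pair that showed no
   matching QTL); an unknown A-strain allele can never establish a pass;
3. score each surviving gene 0/1/2: one point for membership in the
   keyword-evidence (PosMed) list, one point for being regulated in the
   microarray analysis at either age.

Genes not present on the array ("NP") have regulated flags false - absence
of evidence, not fold change 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffexpr import call_regulated
from .io_formats import GeneLocus, SnpRecord, UNKNOWN_ALLELE

logger = logging.getLogger(__name__)

__all__ = [
    "QtlInterval",
    "CHR6_QTL",
    "CHR10_QTL",
    "map_genes_to_interval",
    "haplotype_filter",
    "score_candidate",
    "build_candidate_table",
    "load_reference_table",
    "score_reference_table",
]

NP_SENTINEL = "NP"  # gene not present on the array


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).strip().removeprefix("chr").removeprefix("Chr")
    return c


@dataclass(frozen=True)
class QtlInterval:
    chromosome: str
    start_mb: float
    end_mb: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start_mb < self.end_mb:
            raise ValueError(f"{self.name}: need start < end")
        object.__setattr__(self, "chromosome", _norm_chrom(self.chromosome))


# The two refined ageRD QTL from the B6a x C cross.
CHR6_QTL = QtlInterval("6", 77.5, 93.0, name="Chr6_ageRD")
CHR10_QTL = QtlInterval("10", 15.4, 20.8, name="Chr10_ageRD")


def map_genes_to_interval(loci: Sequence[GeneLocus],
                          interval: QtlInterval) -> set[str]:
    """Genes whose locus overlaps the closed interval on the same chromosome.

    Chromosome naming conventions ("chr10" vs "10") are normalized; a gene
    touching the boundary is included (any-overlap on closed intervals).
    """
    out = set()
    for loc in loci:
        if _norm_chrom(loc.chromosome) != interval.chromosome:
            continue
        if loc.start_mb <= interval.end_mb and loc.end_mb >= interval.start_mb:
            out.add(loc.gene_id)
    return out


def snp_fits_haplotype(snp: SnpRecord) -> bool:
    """True iff the SNP has B6 != C and A != C, with the A allele known."""
    if snp.allele_A == UNKNOWN_ALLELE:
        return False
    return snp.allele_B6 != snp.allele_C and snp.allele_A != snp.allele_C


def haplotype_filter(snps: Iterable[SnpRecord]) -> dict[str, bool]:
    """Per-gene pass flag: the gene passes if >= 1 of its SNPs fits the haplotype."""
    out: dict[str, bool] = {}
    for snp in snps:
        out.setdefault(snp.gene_id, False)
        if snp_fits_haplotype(snp):
            out[snp.gene_id] = True
    return out


def score_candidate(posmed: bool, regulated_4m: bool, regulated_8m: bool) -> int:
    """Evidence score: I[PosMed member] + I[regulated at either age] in {0,1,2}."""
    return int(bool(posmed)) + int(bool(regulated_4m) or bool(regulated_8m))


def build_candidate_table(
    loci: Sequence[GeneLocus],
    intervals: Sequence[QtlInterval],
    snps: Iterable[SnpRecord],
    posmed_genes: set[str],
    regulated_4m: Mapping[str, bool],
    regulated_8m: Mapping[str, bool],
) -> pd.DataFrame:
    """One row per haplotype-passing gene inside any QTL interval.

    ``regulated_4m/8m`` map gene -> regulated call from the microarray
    comparisons; genes absent from the maps are treated as not present on
    the array (regulated false). Output is sorted by interval, then score
    descending, then gene id; scoring is a pure function of the inputs.
    """
    hap = haplotype_filter(snps)
    locus_genes = {loc.gene_id for loc in loci}
    orphans = sorted(set(hap) - locus_genes)
    if orphans:
        logger.warning("SNP-table genes missing from the locus table, excluded: %s",
                       orphans)
    rows = []
    for interval in intervals:
        in_interval = map_genes_to_interval(loci, interval)
        for gene in sorted(in_interval):
            if not hap.get(gene, False):
                continue
            pm = gene in posmed_genes
            r4 = bool(regulated_4m.get(gene, False))
            r8 = bool(regulated_8m.get(gene, False))
            rows.append(
                {
                    "gene": gene,
                    "interval": interval.name or f"{interval.chromosome}:"
                    f"{interval.start_mb}-{interval.end_mb}",
                    "in_qtl": True,
                    "haplotype_pass": True,
                    "posmed": pm,
                    "regulated_4m": r4,
                    "regulated_8m": r8,
                    "score": score_candidate(pm, r4, r8),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene", "interval", "in_qtl", "haplotype_pass", "posmed",
                 "regulated_4m", "regulated_8m", "score"],
    )
    if not df.empty:
        df = df.sort_values(["interval", "score", "gene"],
                            ascending=[True, False, True]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# transcribed reference tables (the published Chr 6 / Chr 10 candidate lists)


def load_reference_table(which: str | Path) -> pd.DataFrame:
    """Load a shipped reference candidate table ("table3" or "table5"), or a path.

    Columns: gene, posmed (yes/no), fc_4m, fc_8m (linear fold change or the
    "NP" sentinel for genes not on the array), score_printed (the published
    "N criteria" value, carried for cross-checking only).
    """
    if which in ("table3", "table5"):
        ref = resources.files("retqtl").joinpath(f"data/{which}.tsv")
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#")
    else:
        df = pd.read_csv(which, sep="\t", comment="#")
    required = {"gene", "posmed", "fc_4m", "fc_8m", "score_printed"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference table needs columns {sorted(required)}")
    return df


def _regulated_from_fc(token) -> bool:
    if str(token).strip() == NP_SENTINEL:
        return False
    return bool(call_regulated(float(token), 0.0))  # FDR already established


def score_reference_table(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute the evidence score for every row of a reference table.

    Regulation is derived from the printed fold changes (FC >= 1.2 or
    FC <= 0.8; the published tables list only genes whose calls met the FDR
    bound, so the fold-change rule alone decides). Adds columns
    regulated_4m, regulated_8m, score.
    """
    out = df.copy()
    out["posmed_flag"] = out["posmed"].astype(str).str.strip().str.lower() == "yes"
    out["regulated_4m"] = out["fc_4m"].map(_regulated_from_fc)
    out["regulated_8m"] = out["fc_8m"].map(_regulated_from_fc)
    out["score"] = [
        score_candidate(p, r4, r8)
        for p, r4, r8 in zip(out["posmed_flag"], out["regulated_4m"],
                             out["regulated_8m"])
    ]
    return out
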