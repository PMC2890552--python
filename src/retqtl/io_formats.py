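"""Readers and writers for every external table the pipeline touches.

All readers validate strictly and report row counts; none of them compute
anything. The canonical dialects are plain named-column TSV/CSV so the
pipeline never depends on scanner software, with a GenePix-subset (GPR-style)
reader mapped onto the same in-memory chip object.

Conventions fixed here and relied on downstream:

* ch1 is the Cy3 channel and ch2 is Cy5, so ``log2(ch2/ch1)`` is the
  Cy5/Cy3 ratio.
* Genomic coordinates are megabases, 1-based, closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "Spot",
    "TwoColorChip",
    "ChipDesign",
    "GeneLocus",
    "SnpRecord",
    "FormatError",
    "REGION_CLASSES",
    "read_chip_table",
    "write_chip_table",
    "read_gpr_table",
    "read_design",
    "write_design",
    "read_locus_table",
    "write_locus_table",
    "read_snp_table",
    "write_snp_table",
    "read_evidence_list",
    "write_evidence_list",
    "read_qpcr_table",
    "read_onl_table",
    "load_config",
]


class FormatError(ValueError):
    """An input table violates its documented dialect."""


class Orientation(str, Enum):
    """Dye orientation of one hybridization in the dye swap."""

    C_ON_CY5 = "C_on_Cy5"  # C labeled Cy5 (ch2), B6a labeled Cy3 (ch1)
    B6A_ON_CY5 = "B6a_on_Cy5"


@dataclass(frozen=True)
class Spot:
    probe_id: str
    gene_id: str
    ch1: float  # Cy3 intensity
    ch2: float  # Cy5 intensity
    flagged: bool = False


@dataclass
class TwoColorChip:
    """One array's spot intensities in both channels plus design metadata."""

    chip_id: str
    orientation: Orientation
    age_months: int
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_months not in (4, 8):
            raise ValueError(f"age_months must be 4 or 8, got {self.age_months}")
        seen: dict[str, int] = {}
        dups = []
        for s in self.spots:
            if s.probe_id in seen:
                dups.append(s.probe_id)
            seen[s.probe_id] = 1
            if not (s.ch1 >= 0 and s.ch2 >= 0):
                raise ValueError(
                    f"chip {self.chip_id}: negative or non-finite intensity on "
                    f"probe {s.probe_id}"
                )
        if dups:
            raise FormatError(
                f"chip {self.chip_id}: duplicate probe ids: {sorted(set(dups))}"
            )

    @property
    def n_flagged(self) -> int:
        return sum(s.flagged for s in self.spots)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe": [s.probe_id for s in self.spots],
                "gene": [s.gene_id for s in self.spots],
                "ch1": [s.ch1 for s in self.spots],
                "ch2": [s.ch2 for s in self.spots],
                "flag": [int(s.flagged) for s in self.spots],
            }
        )


@dataclass
class ChipDesign:
    """Per-chip orientation and age for the whole experiment.

    The canonical study design is 4 chips per orientation x age cell
    (16 chips total); any balanced design with >= 2 chips per cell is
    accepted.
    """

    entries: pd.DataFrame  # index chip_id; columns orientation, age_months

    def __post_init__(self) -> None:
        required = {"orientation", "age_months"}
        if not required.issubset(self.entries.columns):
            raise FormatError(f"design sheet needs columns {sorted(required)}")
        if self.entries.index.duplicated().any():
            raise FormatError("duplicate chip_id in design sheet")
        counts = self.entries.groupby(["orientation", "age_months"]).size()
        if len(counts) != 4:
            raise FormatError(
                "design must cover both orientations at both ages "
                f"(got cells {list(counts.index)})"
            )
        if counts.min() < 2:
            raise FormatError("need >= 2 chips per orientation x age cell")
        if counts.nunique() != 1:
            raise FormatError("design must be balanced across cells")

    @property
    def chip_ids(self) -> list[str]:
        return list(self.entries.index)

    def chips_with(self, orientation: Orientation | None = None,
                   age_months: int | None = None) -> list[str]:
        sel = pd.Series(True, index=self.entries.index)
        if orientation is not None:
            sel &= self.entries["orientation"] == orientation.value
        if age_months is not None:
            sel &= self.entries["age_months"] == age_months
        return list(self.entries.index[sel])

    def orientation_of(self, chip_id: str) -> Orientation:
        return Orientation(self.entries.loc[chip_id, "orientation"])

    def age_of(self, chip_id: str) -> int:
        return int(self.entries.loc[chip_id, "age_months"])


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start_mb: float
    end_mb: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_mb <= self.end_mb):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start_mb <= end_mb, got "
                f"{self.start_mb}-{self.end_mb}"
            )


REGION_CLASSES = ("nonsyn", "syn", "utr5", "utr3", "intron", "flanking")
_ALLELE_CHARS = set("ACGT-")
UNKNOWN_ALLELE = "?"


def _validate_allele(token: str, *, allow_unknown: bool) -> str:
    token = token.strip()
    if token == UNKNOWN_ALLELE:
        if allow_unknown:
            return token
        raise FormatError("unknown allele '?' only permitted for strain A")
    if token and all(c in _ALLELE_CHARS for c in token.upper()):
        return token.upper()
    raise FormatError(f"invalid allele token {token!r}")


@dataclass(frozen=True)
class SnpRecord:
    """One reported polymorphism among the B6(a), C and A strains."""

    gene_id: str
    region_class: str
    allele_B6: str
    allele_C: str
    allele_A: str  # may be "?" when the A-strain allele is unreported

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise FormatError(
                f"{self.gene_id}: region_class {self.region_class!r} not in "
                f"{REGION_CLASSES}"
            )
        object.__setattr__(self, "allele_B6",
                           _validate_allele(self.allele_B6, allow_unknown=False))
        object.__setattr__(self, "allele_C",
                           _validate_allele(self.allele_C, allow_unknown=False))
        object.__setattr__(self, "allele_A",
                           _validate_allele(self.allele_A, allow_unknown=True))


# ---------------------------------------------------------------------------
# chip tables


def _read_delim(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_chip_table(path: str | Path, chip_id: str,
                    orientation: Orientation, age_months: int) -> TwoColorChip:
    """Read one chip's canonical TSV (columns probe, gene, ch1, ch2[, flag]).

    Flagged or nonpositive-intensity spots stay in the object; they are
    turned into missing ratios downstream, never dropped here.
    """
    df = _read_delim(path, "\t")
    for col in ("probe", "gene", "ch1", "ch2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    flags = df["flag"].astype(int).astype(bool) if "flag" in df.columns else \
        pd.Series(False, index=df.index)
    spots = [
        Spot(str(r.probe), str(r.gene), float(r.ch1), float(r.ch2), bool(f))
        for r, f in zip(df.itertuples(index=False), flags)
    ]
    chip = TwoColorChip(chip_id, orientation, age_months, spots)
    logger.info("read %s: %d spots (%d flagged)", path, len(spots), chip.n_flagged)
    return chip


def write_chip_table(chip: TwoColorChip, path: str | Path) -> None:
    chip.to_frame().to_csv(path, sep="\t", index=False)


_GPR_COLUMN_MAP = {
    "ID": "probe",
    "Name": "gene",
    "F532 Mean": "ch1",  # Cy3
    "F635 Mean": "ch2",  # Cy5
    "Flags": "flag",
}


def read_gpr_table(path: str | Path, chip_id: str,
                   orientation: Orientation, age_months: int) -> TwoColorChip:
    """Alternate reader for a GenePix-derived export subset.

    Accepts a tab table whose header uses the scanner's column names
    ("F532 Mean"/"F635 Mean" style); negative GenePix flag values mark bad
    spots. Maps onto the same :class:`TwoColorChip` as the canonical dialect.
    """
    df = _read_delim(path, "\t")
    missing = [c for c in ("ID", "F532 Mean", "F635 Mean") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame()
    for src, dst in _GPR_COLUMN_MAP.items():
        if src in df.columns:
            out[dst] = df[src]
    if "gene" not in out.columns:
        out["gene"] = out["probe"]
    spots = []
    for r in out.itertuples(index=False):
        flagged = bool(getattr(r, "flag", 0) and float(r.flag) < 0)
        spots.append(Spot(str(r.probe), str(r.gene),
                          max(float(r.ch1), 0.0), max(float(r.ch2), 0.0), flagged))
    return TwoColorChip(chip_id, orientation, age_months, spots)


def read_design(path: str | Path) -> ChipDesign:
    """Design sheet CSV with columns chip_id, orientation, age_months."""
    df = _read_delim(path, ",")
    for col in ("chip_id", "orientation", "age_months"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad = set(df["orientation"]) - {o.value for o in Orientation}
    if bad:
        raise FormatError(f"{path}: unknown orientation values {sorted(bad)}")
    entries = df.set_index("chip_id")[["orientation", "age_months"]]
    entries["age_months"] = entries["age_months"].astype(int)
    return ChipDesign(entries)


def write_design(design: ChipDesign, path: str | Path) -> None:
    design.entries.reset_index().rename(columns={"index": "chip_id"}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# loci, SNPs, evidence lists


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """BED-like locus file: chrom, start, end, gene (tab separated, bp).

    Base-pair coordinates are converted to megabases on read. A header line
    is optional; it is detected by non-numeric start/end fields.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{i + 1}: expected 4 columns, got {len(parts)}")
            chrom, start, end, gene = parts[:4]
            if i == 0 and not start.replace(".", "").isdigit():
                continue  # header
            rows.append(GeneLocus(gene, chrom.removeprefix("chr"),
                                  float(start) / 1e6, float(end) / 1e6))
    logger.info("read %s: %d loci", path, len(rows))
    return rows


def write_locus_table(loci: Sequence[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chromosome}\t{loc.start_mb * 1e6:.0f}\t"
                     f"{loc.end_mb * 1e6:.0f}\t{loc.gene_id}\n")


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """SNP CSV: gene, region_class, allele_B6, allele_C, allele_A.

    An unreported A-strain allele is written "?" and preserved as unknown,
    never guessed. Rows with alleles outside {A,C,G,T,-,multi-base,?} are
    rejected with an error naming the offender.
    """
    df = _read_delim(path, ",")
    if df.empty:
        logger.warning("read %s: empty SNP table", path)
        return []
    for col in ("gene", "region_class", "allele_B6", "allele_C", "allele_A"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = [
        SnpRecord(str(r.gene), str(r.region_class), str(r.allele_B6),
                  str(r.allele_C), str(r.allele_A))
        for r in df.itertuples(index=False)
    ]
    logger.info("read %s: %d SNP records accepted", path, len(records))
    return records


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [s.gene_id for s in snps],
            "region_class": [s.region_class for s in snps],
            "allele_B6": [s.allele_B6 for s in snps],
            "allele_C": [s.allele_C for s in snps],
            "allele_A": [s.allele_A for s in snps],
        }
    ).to_csv(path, index=False)


def read_evidence_list(path: str | Path, source: str = "evidence") -> set[str]:
    """Plain-text keyword-evidence gene list, one gene per line; set semantics."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    logger.info("read %s (%s): %d unique genes", path, source, len(genes))
    return genes


def write_evidence_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# qPCR and ONL tables (consumed by the qpcr / phenotype modules)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Ct table CSV: gene, strain, age, replicate, well, ct_target, ct_reference.

    One row per technical well; `replicate` indexes the biological pool.
    """
    df = _read_delim(path, ",")
    required = ("gene", "strain", "age", "replicate", "well",
                "ct_target", "ct_reference")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("ct_target", "ct_reference"):
        vals = df[col].dropna()
        if ((vals <= 0) | (vals >= 45)).any():
            raise FormatError(f"{path}: {col} outside (0, 45)")
    return df


def read_onl_table(path: str | Path) -> pd.DataFrame:
    """Long-format ONL thickness CSV.

    Columns: animal, genotype, hemisphere (superior/inferior), set (1-9),
    position (1-3), thickness_um. Missing slots (retinal tears) may simply
    be absent.
    """
    df = _read_delim(path, ",")
    required = ("animal", "genotype", "hemisphere", "set", "position",
                "thickness_um")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if (df["thickness_um"].dropna() <= 0).any():
        raise FormatError(f"{path}: thickness must be positive")
    return df


def load_config(path: str | Path) -> dict:
    """Structured YAML config mapping input names to paths and parameters."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
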