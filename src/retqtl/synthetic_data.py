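"""Seeded generators for every input the pipeline consumes, with ground truth.

The two-color generator emulates the study design: a balanced dye swap over
two strains (C vs B6a) at two ages (4 and 8 months), four chips per
orientation x age cell (16 chips), per-gene strain effects in log2 units,
an intensity-dependent dye-bias curve d(A), a per-gene (sequence-specific)
dye effect D_g shared by both orientations, per-chip scale differences,
Gaussian spot noise and independent per-spot missingness flagged in a flag
column (never blank cells).

Spot intensities are reconstructed from (M, A): ``log2 ch1 = A - M/2``,
``log2 ch2 = A + M/2`` with A ~ Uniform(6, 14) log2 units (a typical spotted
array intensity range) and, for a chip with orientation sign ``o`` (+1 when
C is on Cy5) and scale ``c``,

    M = c * (o * s_g(age) + noise) + d(A) + D_g .

The default intensity-dependent bias is ``d(A) = 0.4 sin((A - 6) / 2.5)``,
nonlinear on purpose so the Lowess step has work to do.

Every generator is deterministic given its seed (identical outputs,
byte-identical files) and carries a :class:`SimTruth` so downstream recovery
tests compare against planted truth, never hard-coded constants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ChipDesign,
    Orientation,
    SnpRecord,
    Spot,
    TwoColorChip,
    write_chip_table,
    write_design,
    write_snp_table,
)
from .phenotype import N_POSITIONS, N_SETS, OnlProfile

__all__ = [
    "SimTruth",
    "make_design",
    "gen_two_color_experiment",
    "gen_snp_table",
    "gen_go_annotation",
    "gen_qpcr",
    "gen_onl",
    "write_experiment",
]


@dataclass
class SimTruth:
    """Planted ground truth for one simulated dataset; JSON-serializable."""

    master_seed: int
    strain_effect_4m: dict[str, float] = field(default_factory=dict)
    strain_effect_8m: dict[str, float] = field(default_factory=dict)
    gene_dye_effect: dict[str, float] = field(default_factory=dict)
    dye_bias: dict = field(default_factory=dict)  # {"id": ..., params...}
    chip_scale: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    enriched_terms: list[str] = field(default_factory=list)
    haplotype_pass_genes: list[str] = field(default_factory=list)
    qpcr_folds: dict[str, float] = field(default_factory=dict)
    onl_genotype_means: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _dye_curve(a: np.ndarray, dye_bias: dict) -> np.ndarray:
    kind = dye_bias.get("id", "sine")
    if kind == "sine":
        amp = float(dye_bias.get("amplitude", 0.4))
        width = float(dye_bias.get("width", 2.5))
        return amp * np.sin((a - 6.0) / width)
    if kind == "none":
        return np.zeros_like(a)
    raise ValueError(f"unknown dye-bias curve {dye_bias!r}")


def make_design(n_chips_per_cell: int = 4) -> ChipDesign:
    """Balanced dye-swap design: n chips per orientation x age cell."""
    rows = []
    k = 0
    for orient in Orientation:
        for age in (4, 8):
            for _ in range(n_chips_per_cell):
                k += 1
                rows.append((f"chip{k:02d}", orient.value, age))
    df = pd.DataFrame(rows, columns=["chip_id", "orientation", "age_months"])
    return ChipDesign(df.set_index("chip_id"))


def gen_two_color_experiment(
    n_genes: int = 500,
    n_chips_per_cell: int = 4,
    effect_frac: float = 0.1,
    effect_size: float = 1.0,
    effect_ages: str = "both",  # "both" | "m4_only" | "m8_only"
    dye_bias: dict | None = None,
    gene_dye_sd: float = 0.3,
    chip_scale_sd: float = 0.1,
    sigma: float = 0.2,
    missing_rate: float = 0.02,
    probes_per_gene: int = 1,
    seed: int = 0,
) -> tuple[list[TwoColorChip], ChipDesign, SimTruth]:
    """Simulate a balanced dye-swap two-color experiment with known truth.

    ``effect_frac`` of the genes receive a strain effect of magnitude
    ``effect_size`` log2 units with random sign; ``effect_ages`` restricts
    the effect to one age (the age-dependency scenario). ``chip_scale_sd``
    is the SD of the per-chip log-scale factor; ``gene_dye_sd`` the SD of
    the per-gene dye effect D_g.
    """
    if not 0.0 <= effect_frac <= 1.0:
        raise ValueError(f"effect_frac must be in [0, 1], got {effect_frac}")
    if effect_ages not in ("both", "m4_only", "m8_only"):
        raise ValueError(f"unknown effect_ages {effect_ages!r}")
    dye_bias = dict(dye_bias) if dye_bias is not None else {
        "id": "sine", "amplitude": 0.4, "width": 2.5}
    rng = np.random.default_rng(seed)

    genes = [f"g{i:04d}" for i in range(n_genes)]
    base_a = rng.uniform(6.0, 14.0, size=n_genes)
    n_effect = int(round(effect_frac * n_genes))
    effect_idx = rng.choice(n_genes, size=n_effect, replace=False)
    s = np.zeros(n_genes)
    s[effect_idx] = effect_size * rng.choice([-1.0, 1.0], size=n_effect)
    s4 = s.copy() if effect_ages in ("both", "m4_only") else np.zeros(n_genes)
    s8 = s.copy() if effect_ages in ("both", "m8_only") else np.zeros(n_genes)
    d_gene = rng.normal(0.0, gene_dye_sd, size=n_genes) if gene_dye_sd > 0 \
        else np.zeros(n_genes)

    design = make_design(n_chips_per_cell)
    scales = {c: float(np.exp(rng.normal(0.0, chip_scale_sd)))
              for c in design.chip_ids}

    chips: list[TwoColorChip] = []
    for chip_id in design.chip_ids:
        orient = design.orientation_of(chip_id)
        age = design.age_of(chip_id)
        o = 1.0 if orient is Orientation.C_ON_CY5 else -1.0
        s_age = s4 if age == 4 else s8
        a = base_a + (rng.normal(0.0, 0.1, size=n_genes) if sigma > 0 else 0.0)
        spots = []
        for rep in range(probes_per_gene):
            noise = rng.normal(0.0, sigma, size=n_genes) if sigma > 0 \
                else np.zeros(n_genes)
            m = scales[chip_id] * (o * s_age + noise) + _dye_curve(a, dye_bias) \
                + d_gene
            log_ch1 = a - m / 2.0
            log_ch2 = a + m / 2.0
            flags = rng.random(n_genes) < missing_rate
            for i, g in enumerate(genes):
                spots.append(Spot(f"p{rep}_{g}", g,
                                  float(2.0 ** log_ch1[i]),
                                  float(2.0 ** log_ch2[i]),
                                  bool(flags[i])))
        chips.append(TwoColorChip(chip_id, orient, age, spots))

    truth = SimTruth(
        master_seed=seed,
        strain_effect_4m=dict(zip(genes, map(float, s4))),
        strain_effect_8m=dict(zip(genes, map(float, s8))),
        gene_dye_effect=dict(zip(genes, map(float, d_gene))),
        dye_bias=dye_bias,
        chip_scale=scales,
        missing_rate=missing_rate,
    )
    return chips, design, truth


def gen_snp_table(n_genes: int = 100, pass_frac: float = 0.3,
                  seed: int = 0) -> tuple[list[SnpRecord], SimTruth]:
    """SNP records with a planted fraction of haplotype-passing genes.

    Passing genes get >= 1 SNP with B6 != C and A != C; the remainder get
    only failing SNPs (B6 == C, or A == C, or an unknown A allele that would
    otherwise pass - unknowns must never establish a pass).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    n_pass = int(round(pass_frac * n_genes))
    pass_set = set(rng.choice(genes, size=n_pass, replace=False))
    classes = list(("intron", "nonsyn", "syn", "utr3", "utr5", "flanking"))
    bases = "ACGT"
    records: list[SnpRecord] = []
    for g in genes:
        region = classes[rng.integers(len(classes))]
        if g in pass_set:
            b6, c = rng.choice(list(bases), size=2, replace=False)
            records.append(SnpRecord(g, region, b6, c, b6))
            if rng.random() < 0.3:  # extra failing SNP on a passing gene
                records.append(SnpRecord(g, "syn", "A", "A", "A"))
        else:
            mode = rng.integers(3)
            b6, c = rng.choice(list(bases), size=2, replace=False)
            if mode == 0:  # B6 == C
                records.append(SnpRecord(g, region, b6, b6, c))
            elif mode == 1:  # A == C
                records.append(SnpRecord(g, region, b6, c, c))
            else:  # unknown A allele, would pass if known
                records.append(SnpRecord(g, region, b6, c, "?"))
    truth = SimTruth(master_seed=seed, haplotype_pass_genes=sorted(pass_set))
    return records, truth


def gen_go_annotation(
    n_genes: int = 500,
    n_terms: int = 40,
    term_size: tuple[int, int] = (10, 40),
    planted_term_size: int = 20,
    planted_changed_frac: float = 0.8,
    background_changed_frac: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, set[str]], list[str], set[str], SimTruth]:
    """Annotation with one planted enriched term among background terms.

    Returns (gene -> terms, measured gene list, changed gene set, truth).
    Genes in the planted term are changed at ``planted_changed_frac``; all
    other genes at ``background_changed_frac``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    terms = [f"T{i:03d}" for i in range(n_terms)]
    planted = terms[0]
    gene_terms: dict[str, set[str]] = {g: set() for g in genes}
    planted_genes = list(rng.choice(genes, size=planted_term_size, replace=False))
    for g in planted_genes:
        gene_terms[g].add(planted)
    for t in terms[1:]:
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        for g in rng.choice(genes, size=size, replace=False):
            gene_terms[g].add(t)
    changed = set()
    planted_set = set(planted_genes)
    for g in genes:
        p = planted_changed_frac if g in planted_set else background_changed_frac
        if rng.random() < p:
            changed.add(g)
    truth = SimTruth(master_seed=seed, enriched_terms=[planted])
    return gene_terms, genes, changed, truth


def gen_qpcr(
    folds: dict[tuple[str, int], float] | None = None,
    sigma_ct: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 3,
    ae: float = 1.0,
    gene: str = "Tnfaip3",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Ct table with planted fold changes per strain x age group.

    Folds are relative to the (B6a, 4 months) calibrator, whose fold is 1;
    planted via ``dCt_group = dCt_cal - log2(fold) / log2(1 + AE)``.
    ``sigma_ct`` is the biological-replicate Ct noise; technical triplicate
    wells add smaller (0.05 cycle) pipetting noise.
    """
    if folds is None:
        folds = {("B6a", 4): 1.0, ("B6a", 8): 1.0, ("C", 4): 1.0, ("C", 8): 2.0}
    if folds.get(("B6a", 4), 1.0) != 1.0:
        raise ValueError("calibrator (B6a, 4) fold must be 1")
    rng = np.random.default_rng(seed)
    dct_cal = 5.0
    rows = []
    for (strain, age), fold in sorted(folds.items()):
        dct = dct_cal - np.log2(fold) / np.log2(1.0 + ae)
        for rep in range(1, n_bio + 1):
            ct_ref = 18.0 + rng.normal(0.0, sigma_ct)
            ct_tgt = ct_ref + dct + rng.normal(0.0, sigma_ct)
            for well in range(1, n_tech + 1):
                rows.append(
                    {
                        "gene": gene,
                        "strain": strain,
                        "age": age,
                        "replicate": rep,
                        "well": well,
                        "ct_target": ct_tgt + rng.normal(0.0, 0.05),
                        "ct_reference": ct_ref + rng.normal(0.0, 0.05),
                    }
                )
    truth = SimTruth(
        master_seed=seed,
        qpcr_folds={f"{s}_{a}": float(f) for (s, a), f in folds.items()},
    )
    return pd.DataFrame(rows), truth


def gen_onl(
    genotype_means: dict[str, float] | None = None,
    sigma_animal: float = 2.0,
    sigma_slot: float = 1.5,
    n_per_group: int = 20,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[OnlProfile], SimTruth]:
    """ONL profiles with planted per-genotype mean thickness (um).

    The default means (44, 40, 36 um for B6a/B6a, HET, C/C) encode a purely
    additive allele effect with the B6a allele protective. ``sigma_animal``
    is the between-animal SD of the true mean; ``sigma_slot`` the
    within-section measurement noise.
    """
    if genotype_means is None:
        genotype_means = {"B6a/B6a": 44.0, "HET": 40.0, "C/C": 36.0}
    rng = np.random.default_rng(seed)
    profiles = []
    k = 0
    for genotype, mu in sorted(genotype_means.items()):
        for _ in range(n_per_group):
            k += 1
            animal_mean = rng.normal(mu, sigma_animal)
            slots = rng.normal(animal_mean, sigma_slot,
                               size=(2, N_SETS, N_POSITIONS))
            slots = np.clip(slots, 1.0, None)  # thickness must stay positive
            if missing_rate > 0:
                mask = rng.random(slots.shape) < missing_rate
                slots[mask] = np.nan
            profiles.append(OnlProfile(f"animal{k:03d}", genotype, slots))
    truth = SimTruth(master_seed=seed,
                     onl_genotype_means={g: float(m)
                                         for g, m in genotype_means.items()})
    return profiles, truth


def write_experiment(outdir: str | Path, chips: list[TwoColorChip],
                     design: ChipDesign, truth: SimTruth) -> None:
    """Write a runnable dataset directory: chips/*.tsv, design.csv, truth.json."""
    outdir = Path(outdir)
    (outdir / "chips").mkdir(parents=True, exist_ok=True)
    for chip in chips:
        write_chip_table(chip, outdir / "chips" / f"{chip.chip_id}.tsv")
    write_design(design, outdir / "design.csv")
    truth.to_json(outdir / "truth.json")
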