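"""Outer nuclear layer (ONL) thickness summarization and genotype association.

The sampling protocol measures each retinal section in two hemispheres
(superior/inferior), nine 250-um sets per hemisphere, three positions per
set: 54 measurement slots per section. ONL thickness indexes photoreceptor
survival. The per-animal mean over non-missing slots is the unit of
analysis (slots within an eye are not independent); missing slots (retinal
tears) are allowed and masked.

Genotype association compares the per-animal means across marker genotypes
(homozygous B6a, heterozygous, homozygous C - or +/+ vs +/- for knockout
tests) with a one-way ANOVA and Holm-Sidak pairwise comparisons, and
reports the additivity gap: mean(HET) - (mean(B6a/B6a) + mean(C/C)) / 2,
zero under a purely additive allele effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpcr import anova_holm_sidak

logger = logging.getLogger(__name__)

__all__ = [
    "HEMISPHERES",
    "N_SETS",
    "N_POSITIONS",
    "SLOTS_PER_SECTION",
    "OnlProfile",
    "onl_mean",
    "profiles_from_table",
    "genotype_association",
]

HEMISPHERES = ("superior", "inferior")
N_SETS = 9
N_POSITIONS = 3
SLOTS_PER_SECTION = len(HEMISPHERES) * N_SETS * N_POSITIONS  # 54


@dataclass
class OnlProfile:
    """One animal's ONL measurements: 2 hemispheres x 9 sets x 3 positions (um)."""

    animal_id: str
    genotype: str
    measurements: np.ndarray = field(
        default_factory=lambda: np.full((2, N_SETS, N_POSITIONS), np.nan))

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, float)
        if self.measurements.shape != (2, N_SETS, N_POSITIONS):
            raise ValueError(
                f"measurements must be shape (2, {N_SETS}, {N_POSITIONS}), "
                f"got {self.measurements.shape}")
        if np.nanmin(self.measurements, initial=np.inf) <= 0:
            raise ValueError(f"{self.animal_id}: thickness must be positive")


def onl_mean(profile: OnlProfile) -> float:
    """Arithmetic mean thickness over the non-missing measurement slots."""
    vals = profile.measurements
    if np.all(np.isnan(vals)):
        raise ValueError(f"{profile.animal_id}: no measurements")
    return float(np.nanmean(vals))


def profiles_from_table(df: pd.DataFrame) -> list[OnlProfile]:
    """Assemble per-animal profiles from the long-format ONL table."""
    hemi_idx = {h: i for i, h in enumerate(HEMISPHERES)}
    profiles = []
    for (animal, genotype), g in df.groupby(["animal", "genotype"], sort=True):
        arr = np.full((2, N_SETS, N_POSITIONS), np.nan)
        for r in g.itertuples(index=False):
            h = hemi_idx[str(r.hemisphere).lower()]
            s, p = int(r.set) - 1, int(r.position) - 1
            if not (0 <= s < N_SETS and 0 <= p < N_POSITIONS):
                raise ValueError(f"{animal}: set/position out of range ({r.set}, {r.position})")
            arr[h, s, p] = float(r.thickness_um)
        profiles.append(OnlProfile(str(animal), str(genotype), arr))
    return profiles


def genotype_association(profiles: list[OnlProfile],
                         het_label: str = "HET",
                         homo_labels: tuple[str, str] = ("B6a/B6a", "C/C"),
                         ) -> tuple[float, pd.DataFrame, float]:
    """(ANOVA p, Holm-Sidak pairwise p matrix, additivity gap in um).

    Groups animals by genotype on their per-animal mean thickness; genotype
    groups with fewer than 2 animals are excluded with a warning. The
    additivity gap is NaN unless the heterozygote and both homozygote groups
    are present. p values are invariant to um -> mm unit rescaling.
    """
    by_geno: dict[str, list[float]] = {}
    for prof in profiles:
        by_geno.setdefault(prof.genotype, []).append(onl_mean(prof))
    small = [g for g, v in by_geno.items() if len(v) < 2]
    for g in small:
        logger.warning("genotype group %r has n < 2; excluded", g)
        del by_geno[g]
    anova_p, pairwise = anova_holm_sidak(by_geno)
    gap = float("nan")
    if het_label in by_geno and all(h in by_geno for h in homo_labels):
        gap = float(np.mean(by_geno[het_label])
                    - 0.5 * (np.mean(by_geno[homo_labels[0]])
                             + np.mean(by_geno[homo_labels[1]])))
    return anova_p, pairwise, gap
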