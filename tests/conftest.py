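import numpy as np
import pandas as pd
import pytest

from retqtl import normalize
from retqtl import synthetic_data as sim
from retqtl.io_formats import ChipDesign, Orientation, Spot, TwoColorChip


@pytest.fixture(scope="session")
def default_experiment():
    """One canonical 16-chip dye-swap simulation with truth (session-wide)."""
    chips, design, truth = sim.gen_two_color_experiment(n_genes=500, seed=11)
    return chips, design, truth


@pytest.fixture(scope="session")
def normalized_default(default_experiment):
    chips, design, truth = default_experiment
    matrix, audit = normalize.normalize_pipeline(chips, design)
    return matrix, audit, truth


@pytest.fixture()
def tiny_design():
    rows = []
    k = 0
    for orient in Orientation:
        for age in (4, 8):
            for _ in range(2):
                k += 1
                rows.append((f"c{k}", orient.value, age))
    df = pd.DataFrame(rows, columns=["chip_id", "orientation", "age_months"])
    return ChipDesign(df.set_index("chip_id"))


def make_chip(chip_id="c1", orientation=Orientation.C_ON_CY5, age=4, spots=None):
    if spots is None:
        spots = [Spot("p1", "g1", 100.0, 200.0), Spot("p2", "g2", 50.0, 50.0)]
    return TwoColorChip(chip_id, orientation, age, spots)


def matrix_from_values(values: pd.DataFrame, design: ChipDesign,
                       stage: str = "rescaled") -> normalize.RatioMatrix:
    """Hand-built RatioMatrix for unit tests of individual stages."""
    return normalize.RatioMatrix(values, design, stage=stage, level="gene")


@pytest.fixture()
def tiny_design16():
    """Canonical-shape 16-chip design (4 per orientation x age cell)."""
    return sim.make_design(4)
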