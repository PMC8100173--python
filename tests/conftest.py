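import numpy as np
import pytest

from scith.simulate import (
    CellTypeProfile,
    CNASegment,
    SimulationConfig,
    generate_cohort,
)


@pytest.fixture
def neutral_profiles():
    return {
        "Cancer": CellTypeProfile(markers=(), malignant=True),
        "Stromal": CellTypeProfile(markers=()),
    }


@pytest.fixture
def neutral_cfg(neutral_profiles):
    """Copy-neutral, marker-free two-type cohort: one patient, 200+200 cells."""
    return SimulationConfig(
        n_patients=1,
        cell_type_profiles=neutral_profiles,
        n_cells_per_type={"Cancer": 200, "Stromal": 200},
        cna_segments=(),
        lr_signals=(),
        marker_baseline_mean=None,
        seed=7,
    )


@pytest.fixture
def gain_cfg(neutral_profiles):
    """One clone with a fold-2 gain over chr1 genes 100-249, 500+500 cells."""
    return SimulationConfig(
        n_patients=1,
        genes_per_chromosome={"chr1": 400, "chr2": 300, "chr3": 300},
        cell_type_profiles=neutral_profiles,
        n_cells_per_type={"Cancer": 500, "Stromal": 500},
        cna_segments=(CNASegment("chr1", 100, 150, 2.0),),
        lr_signals=(),
        marker_baseline_mean=None,
        seed=11,
    )


@pytest.fixture
def small_cohort(neutral_cfg):
    adatas, truth, gene_order = generate_cohort(neutral_cfg)
    return adatas, truth, gene_order


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
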