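import numpy as np
import pytest

from ctsdm import SimulationDesign, simulate_dataset, synthesize_reference

THREE_CELLS = ("CD4T", "Monocyte", "B-cell")


@pytest.fixture(scope="session")
def small_panel():
    return synthesize_reference(
        p=400,
        cell_types=list(THREE_CELLS),
        mean_hyper=(0.1, 0.9),
        sd_hyper=(0.01, 0.05),
        pure_samples_per_type=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        cell_types=THREE_CELLS,
        fraction_bounds={
            "CD4T": (0.4, 0.6),
            "Monocyte": (0.2, 0.4),
            "B-cell": (0.0, 0.2),
        },
        n=80,
        snr=11.0,
        effects={"CD4T": 30, "Monocyte": 30},
        p=400,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design, small_panel):
    return simulate_dataset(small_design, small_panel, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
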