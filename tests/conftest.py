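import numpy as np
import pytest

from panmethyl.io import BetaMatrix, SampleSheet
from panmethyl.simulate import PlantedModule, SimConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """3 datasets, 400 probes, 80 samples; two shared modules (one planted in
    2/3 datasets), one dataset-specific module."""
    config = SimConfig(
        n_datasets=3,
        probes_per_dataset=400,
        samples_per_dataset=80,
        normal_fraction=0.25,
        shared_modules=(
            PlantedModule(name="m_shift", size=15, tumor_shift=2.0,
                          presence=frozenset({0, 1})),
            PlantedModule(name="m_flat", size=15, presence=frozenset({0, 1})),
        ),
        specific_modules=((2, PlantedModule(name="m_solo", size=15)),),
        noise_sd=0.4,
        seed=11,
    )
    return generate_study(config)


@pytest.fixture
def tiny_bm():
    """5 probes x 6 samples with hand-set values, no missing cells."""
    rng = np.random.default_rng(3)
    vals = rng.uniform(0.05, 0.95, size=(5, 6))
    return BetaMatrix([f"p{i}" for i in range(5)], [f"s{j}" for j in range(6)], vals)


@pytest.fixture
def tiny_sheet():
    return SampleSheet(
        [f"s{j}" for j in range(6)],
        ["tumor", "tumor", "tumor", "normal", "normal", "normal"],
        np.array([50.0, 60.0, 70.0, 55.0, 65.0, np.nan]),
    )
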