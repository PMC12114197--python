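import numpy as np
import pandas as pd
import pytest

from soilemf import AbundanceTable, default_study_design, simulate_experiment
from soilemf.synthetic import CorrelationBlock, ExperimentDesign


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic five-treatment experiment at the default design."""
    return simulate_experiment(default_study_design(seed=11))


@pytest.fixture(scope="session")
def block_design():
    """Single-treatment 30-sample design with a planted positive block."""
    return ExperimentDesign(
        treatment_labels=("A",),
        replicates=30,
        indicator_baselines={"x": (1.0, 0.1)},
        blocks={
            "bacteria": [CorrelationBlock(size=10, sign=1, magnitude=0.8)],
            "fungi": [],
        },
        taxa_counts={"bacteria": 60, "fungi": 20},
        seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_table():
    """Tiny hand-made count table (4 samples x 5 taxa)."""
    counts = pd.DataFrame(
        [
            [10, 0, 3, 1, 1],
            [8, 2, 5, 0, 2],
            [12, 1, 2, 2, 0],
            [9, 3, 4, 1, 1],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"t{i}" for i in range(5)],
    )
    return AbundanceTable(counts)
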