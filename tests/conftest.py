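import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for benchmark_tables

from dtiforge import PlantedConfig, gen_planted_dataset
from dtiforge.datasets import GoldStandardDataset


SMALL_PLANTED = dict(
    n_drugs=16, n_targets=16, n_positives=100,
    min_length=40, max_length=90,
)


@pytest.fixture(scope="session")
def small_planted():
    """A small fully planted (signal 1) dataset for pipeline tests."""
    data = gen_planted_dataset(PlantedConfig(seed=11, signal_strength=1.0,
                                             **SMALL_PLANTED))
    fps = {k: v[0] for k, v in data.fingerprints.items()}
    pssms = {k: v[0] for k, v in data.pssms.items()}
    return data, fps, pssms


@pytest.fixture
def toy_dataset():
    return GoldStandardDataset(
        name="toy",
        drug_ids=[f"D{i}" for i in range(10)],
        target_ids=[f"T{j}" for j in range(10)],
        positives={("D0", "T0"), ("D1", "T2"), ("D3", "T5")},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
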