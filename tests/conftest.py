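"""Shared fixtures: seeded random sequences and a small synthetic dataset."""

import numpy as np
import pytest

from dtikit.io_formats import STANDARD_AA
from dtikit.pipeline import PipelineConfig, build_stage
from dtikit.synthetic_data import PlantedSignalSpec, gen_dataset


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(STANDARD_AA[c] for c in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by read-only tests."""
    return gen_dataset(PlantedSignalSpec(n_proteins=15, n_drugs=10, seed=7))


@pytest.fixture(scope="session")
def small_pairset(small_dataset):
    return build_stage(PipelineConfig(seed=7), dataset=small_dataset)
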