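from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synthdiff as sd
from synthdiff.seqio import SequenceRecord

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230605)


@pytest.fixture(scope="session")
def random_seqs(rng) -> list[str]:
    """30 random sequences, 100-400 bp, varied GC."""
    out = []
    for i in range(30):
        n = int(rng.integers(100, 401))
        gc = float(rng.uniform(0.25, 0.75))
        out.append(random_dna(rng, n, gc))
    return out


@pytest.fixture(scope="session")
def small_dataset() -> sd.LabeledDataset:
    """120 synthetic 350 bp sequences with noise-free planted difficulty."""
    return sd.generate_labeled_dataset(120, length=350, seed=11)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    """(normalizer, train matrix, test matrix, train labels, test labels)
    for the small synthetic dataset; extraction shared across tests."""
    model = sd.SynthesisDifficultyModel.from_dataset(small_dataset)
    normalizer, train, test = model._prepared()
    return normalizer, train, test, model._ytrain, model._ytest


@pytest.fixture()
def record() -> SequenceRecord:
    return SequenceRecord("r1", "ACGT" * 100)
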