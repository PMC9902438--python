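import numpy as np
import pytest

from cubkit.codon_core import CODON_ALPHABET, CodonFrequencies
from cubkit.synthetic_data import (
    ClassProfile,
    base_distribution,
    gen_class_profiles,
    gen_usage_table,
)


@pytest.fixture(scope="session")
def reference() -> CodonFrequencies:
    """A fixed, realistically-spread reference codon usage distribution."""
    return base_distribution(seed=0)


@pytest.fixture(scope="session")
def stopfree_reference() -> CodonFrequencies:
    """A reference with zero mass on stop codons (forces zero-removal)."""
    ref = base_distribution(seed=0).values.copy()
    for stop in ("UGA", "UAG", "UAA"):
        ref[CODON_ALPHABET.index(stop)] = 0.0
    return CodonFrequencies(ref / ref.sum())


def single_signal_profiles(signal_codon: str, shift: float, seed: int,
                           concentration: float = 500.0) -> list[ClassProfile]:
    """Two classes identical except one codon's mean is shifted in class 1."""
    base = gen_class_profiles(2, 0.0, seed=seed, concentration=concentration)
    mean = base[1].mean_frequencies.values.copy()
    mean[CODON_ALPHABET.index(signal_codon)] += shift
    mean /= mean.sum()
    return [base[0], ClassProfile("class1", CodonFrequencies(mean), concentration)]


@pytest.fixture(scope="session")
def small_usage_table():
    """5 well-separated classes, 40 rows each — quick classification fixture."""
    profiles = gen_class_profiles(5, 0.8, seed=11)
    table, truth = gen_usage_table(profiles, 40, seed=11)
    return table, truth


def random_confusion_matrix(rng: np.random.Generator, max_classes: int = 6,
                            max_count: int = 30) -> np.ndarray:
    k = int(rng.integers(2, max_classes + 1))
    m = rng.integers(0, max_count, size=(k, k))
    if m.sum() == 0:
        m[0, 0] = 1
    return m
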