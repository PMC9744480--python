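import numpy as np
import pytest

from gvkernel import GenotypeSite, center_phenotype


def make_random_site(rng: np.random.Generator, n: int) -> GenotypeSite:
    """A site with uniformly random genotype values (may be monomorphic)."""
    return GenotypeSite.from_genotype_values(rng.integers(0, 3, n))


def make_centered(rng: np.random.Generator, n: int):
    return center_phenotype(rng.normal(size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
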