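import numpy as np
import pytest

from racepop.io_genotypes import GenotypeMatrix


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_loci: int,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    dosage = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = -1
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)],
        [f"chr1:{j + 1}:A:G" for j in range(n_loci)],
        dosage,
        np.array(["A"] * n_loci),
        np.array(["G"] * n_loci),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng) -> GenotypeMatrix:
    return random_matrix(rng, 6, 20, missing_rate=0.1)
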