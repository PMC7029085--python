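import numpy as np
import pytest

from snpkin.io_formats import MISSING, GenotypeMatrix, Locus


def make_gm(calls, quals=None, samples=None):
    """GenotypeMatrix from a plain 2-D list/array of dosage codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if samples is None:
        samples = [f"S{i:02d}" for i in range(n)]
    loci = [
        Locus(f"L{k}", "1", k + 1, "A", "G",
              None if quals is None else quals[k])
        for k in range(m)
    ]
    return GenotypeMatrix(samples, loci, calls)


@pytest.fixture
def tiny_gm():
    """5 individuals x 4 loci with one missing call."""
    return make_gm(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 2],
            [2, 0, 1, MISSING],
            [0, 2, 2, 0],
            [1, 1, 1, 1],
        ]
    )


@pytest.fixture(scope="session")
def study_fixture():
    """Default 43-sample study-scale simulation (shared across tests)."""
    from snpkin.pedsim import make_study_fixture

    return make_study_fixture()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251002)
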