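import numpy as np
import pytest

from turnover15n import TRNARef, make_trna_refs


@pytest.fixture(scope="session")
def trna_refs() -> list[TRNARef]:
    """Synthetic 47-species reference set used across tRNA-seq tests."""
    return make_trna_refs(seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_peptide(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(aas, size=length))
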