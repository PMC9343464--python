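import numpy as np
import pytest

from combiseq.barcodes import BarcodeSpec, build_codebook
from combiseq.simulate import make_transcripts

DRUGS_4 = ["Imatinib", "Trametinib", "YM155", "DMSO"]


@pytest.fixture(scope="session")
def spec():
    return BarcodeSpec(seed=42)


@pytest.fixture(scope="session")
def codebook_4x4(spec):
    """Same four drugs on both injection roles, as in a small control screen."""
    return build_codebook(DRUGS_4, DRUGS_4, spec)


@pytest.fixture(scope="session")
def transcripts():
    return make_transcripts(n_genes=40, length=120, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
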