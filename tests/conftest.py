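import pytest

from barnaslip.orf_annotator import annotate
from barnaslip.synthetic_data import GenomeConfig, generate_genome


@pytest.fixture(scope="session")
def bundle():
    """Default barnavirus-like truth genome (the study conditions)."""
    return generate_genome(GenomeConfig(), seed=1)


@pytest.fixture(scope="session")
def arch(bundle):
    return annotate(bundle.genome)
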