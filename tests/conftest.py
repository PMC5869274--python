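import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from indelkit.datasets import GENOTYPE_COUNTS, reconstructed_cohort


@pytest.fixture(scope="session")
def counts_16bp():
    return GENOTYPE_COUNTS["indel16"]


@pytest.fixture(scope="session")
def counts_5bp():
    return GENOTYPE_COUNTS["indel5"]


@pytest.fixture(scope="session")
def cohort():
    """Synthetic per-animal cohort expanded from the published margins."""
    return reconstructed_cohort(seed=0)
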