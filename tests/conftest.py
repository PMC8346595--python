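import pytest

from clonokit.core_model import load_cohort_fixture
from clonokit.synthetic_data import build_toy_reference, make_reference_signatures


@pytest.fixture(scope="session")
def toy_world():
    """(reference chrom->seq, ToyAnnotations) with planted features."""
    return build_toy_reference(seed=0)


@pytest.fixture(scope="session")
def ref_sigs():
    """Eight sparse, well-separated synthetic reference signatures."""
    return make_reference_signatures(8, seed=1)


@pytest.fixture(scope="session")
def cohort_metas():
    return load_cohort_fixture()
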