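import pytest

from pksnrps import constants as C
from pksnrps.bundle import default_bundle
from pksnrps.mining import Thresholds
from pksnrps.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def tiny_cohort(bundle):
    """Three planted BGCs (one per major-clade family), zero mutation."""
    spec = CohortSpec(templates={"Ia-D-1": 1, "II-A": 1, "Ib-C": 1},
                      mutation_rate=0.0, seed=7)
    return spec, generate_cohort(spec, bundle)


@pytest.fixture(scope="session")
def all_templates():
    return sorted(C.KNOWN_CLADES)
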