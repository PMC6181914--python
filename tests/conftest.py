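import pytest

from cpakit.benchmarks import patristic_matrix, random_additive_tree  # noqa: F401
from cpakit.substitution import SubstitutionModel


@pytest.fixture(scope="session")
def lg():
    return SubstitutionModel.lg()


@pytest.fixture(scope="session")
def poisson():
    return SubstitutionModel.poisson()
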