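import pytest

from aopkg.biolink_model import default_hierarchies
from aopkg.fixtures import build_case_study


@pytest.fixture(scope="session")
def hierarchies():
    return default_hierarchies()


@pytest.fixture(scope="session")
def categories(hierarchies):
    return hierarchies[0]


@pytest.fixture(scope="session")
def predicates(hierarchies):
    return hierarchies[1]


@pytest.fixture(scope="session")
def bundle():
    """The committed case-study bundle (built once per session)."""
    return build_case_study()
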