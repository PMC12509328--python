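import pytest

from bispbk.model import SolverConfig
from bispbk.workflow import build_default_parameters


@pytest.fixture(scope="session")
def registry():
    from bispbk.chem import default_registry

    return default_registry()


@pytest.fixture(scope="session")
def physiologies():
    from bispbk.physiology import default_physiologies

    return default_physiologies()


@pytest.fixture(scope="session")
def man_params():
    return build_default_parameters("BPA", "man")


@pytest.fixture(scope="session")
def rat_params():
    return build_default_parameters("BPA", "rat", ehcr=0.5)


@pytest.fixture(scope="session")
def fast_solver():
    """Coarser output grid for speed; solver tolerances unchanged."""
    return SolverConfig(dt_out=0.05)
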