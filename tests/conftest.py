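import pytest

from psgame.asymmetric import AsymmetricParams
from psgame.basic import BasicParams


@pytest.fixture
def basic_baseline() -> BasicParams:
    """Field-baseline single-phenotype parameters."""
    return BasicParams(lam=0.6, alpha=0.40, gamma=1.2, G=15.0)


@pytest.fixture(params=["A", "B", "C"])
def scenario_params(request) -> AsymmetricParams:
    """Baseline asymmetric parameters, one fixture instance per scenario."""
    return AsymmetricParams.scenario(request.param)
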