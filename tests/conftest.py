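import pytest

from nitrokin import InhibitionParams, KineticParams, RedoxTwoStepParams


@pytest.fixture
def nitrofurantoin_params():
    """Global-fit truth for the nitrofurantoin/NADPH surface."""
    return KineticParams(kcat=81.0, Km_A=20.6, Km_B=10.9)


@pytest.fixture
def nitrofurazone_params():
    """Global-fit truth for the nitrofurazone/NADPH surface."""
    return KineticParams(kcat=29.6, Km_A=13.0, Km_B=34.0)


@pytest.fixture
def fmn_inhibition_params():
    """Mixed-inhibition truth: NADPH is substrate A, nitrofurazone B."""
    return InhibitionParams(
        base=KineticParams(kcat=21.4, Km_A=62.0, Km_B=11.0),
        Ki_A=8.0, Ki_B=7.0)


@pytest.fixture
def two_step_truth():
    return RedoxTwoStepParams(E1=-272.0, E2=-268.0, b=0.3)
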