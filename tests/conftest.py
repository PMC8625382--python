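import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from phytokin import (
    DegradationDesign,
    TrueKinetics,
    generate_degradation,
)
from phytokin import reference as ref


@pytest.fixture
def noiseless_tac_series():
    """Exact exponential series at the published TAC rate constants."""
    design = DegradationDesign(noise_cv=0.0, replicates=3, seed=0)
    truth = TrueKinetics(dict(ref.TAC_RATE_CONSTANTS), c0=1.0, analyte="TAC")
    return generate_degradation(design, truth)


@pytest.fixture
def noiseless_single_series(noiseless_tac_series):
    """The 155 °C series (fastest decay) from the noiseless fixture."""
    return [s for s in noiseless_tac_series if s.temperature_c == 155.0][0]
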