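import numpy as np
import pytest

from fungqlv import MaterialModel, ProtocolSpec, ReducedRelaxation, generate_history


@pytest.fixture
def prony_half():
    """One-term Prony series with long-time ratio 0.5 and tau = 1 s."""
    return ReducedRelaxation.one_term(0.5, 1.0)


@pytest.fixture
def smooth_history():
    """Seeded smooth random stretch history on [0, 4] s."""
    return generate_history(ProtocolSpec("random_smooth", amplitude=0.4,
                                         ramp_time=1.0, hold_time=1.0,
                                         n_nodes=101, seed=7))


@pytest.fixture
def pulse_history():
    """C^1 pulse: stretch rises to 1.5, holds, returns exactly to 1."""
    return generate_history(ProtocolSpec("smooth_pulse", amplitude=0.5,
                                         ramp_time=1.0, hold_time=1.0, n_nodes=241))


@pytest.fixture(params=[
    MaterialModel("neo-hookean"),
    MaterialModel("yeoh2", alpha=1.0),
    MaterialModel("mooney-rivlin", gamma=1.0 / 6.0),
    MaterialModel("horgan-murphy", gamma=0.2, kappa=8.0),
    MaterialModel("gent", kappa=8.0, Jm=20.0),
], ids=lambda m: m.name)
def any_model(request):
    return request.param


@pytest.fixture(params=[
    MaterialModel("horgan-murphy", gamma=0.2, kappa=8.0),
    MaterialModel("gent", kappa=8.0, Jm=20.0),
], ids=lambda m: m.name)
def compressible_model(request):
    return request.param
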