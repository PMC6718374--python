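import numpy as np
import pytest

from perfquant.phantom import BolusSpec, PhantomConfig, generate_aif, simulate_protocol


@pytest.fixture(scope="session")
def noise_free_datasets():
    """One noise-free phantom run per flow of the 1-5 mL/g/min grid."""
    out = {}
    for flow in (1.0, 2.0, 3.0, 4.0, 5.0):
        cfg = PhantomConfig(flow=flow, noise_mr_sigma=0.0, noise_pet_cv=0.0)
        out[flow] = simulate_protocol(cfg)
    return out


@pytest.fixture()
def gamma_aif():
    """A single unit-dose gamma-variate bolus on a 0.1-s grid."""
    t = np.arange(0.0, 200.0, 0.1)
    return generate_aif([BolusSpec(dose=1.0, arrival_time=10.0)], t, unit="mmol/L")
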