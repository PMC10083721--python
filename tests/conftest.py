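import numpy as np
import pytest

from caleak import BatemanParams, GroundTruth, ProtocolSpec, Trace, generate_experiment
from caleak.kinetics import bateman_transient

#: Bateman parameters of the control-condition transient reconstruction.
CONTROL = BatemanParams(b_ler=2.40, k_leak=14.55e-3, k_clear=28.34e-3)

#: (k_leak, b_lER, k_depl) for control and the two leak-enhanced states.
CONDITION_TRIPLET = (
    (14.55e-3, 2.40, 6.28e-3),
    (21.03e-3, 2.38, 10.14e-3),
    (30.07e-3, 0.62, 22.51e-3),
)


@pytest.fixture
def control_params() -> BatemanParams:
    return CONTROL


@pytest.fixture
def control_transient_3s(control_params) -> Trace:
    """Noiseless baseline-subtracted control transient, 3 s sampling, t0 at stimulus."""
    t = np.arange(0.0, 601.0, 3.0)
    return Trace(t=t, value=bateman_transient(t, control_params), channel="cyt")


@pytest.fixture
def dual_sensor_experiment():
    """Noiseless paired cyt/ER recording under the store-release protocol."""
    proto = ProtocolSpec(
        protocol_id="tg_zero_ca",
        events=(("TG", 60.0),),
        duration=600.0,
        noise_sd_cyt=0.0,
        noise_sd_er=0.0,
        seed=11,
    )
    truth = GroundTruth(bateman=CONTROL, k_depl=6.28e-3)
    return generate_experiment(proto, truth)
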