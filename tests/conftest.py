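import numpy as np
import pytest

from fusctl.experiment import generate_training_records, train_default_predictor
from fusctl.predict import TrainConfig
from fusctl.simulate import GeneratorParams, SonicationProtocol, SubjectModel
from fusctl.spectral import AEFrame, detect_broadband


@pytest.fixture(scope="session")
def params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def protocol():
    return SonicationProtocol()


@pytest.fixture(scope="session")
def mouse():
    return SubjectModel.default(species="mouse", seed=1, jitter=False)


@pytest.fixture(scope="session")
def rat():
    return SubjectModel.default(species="rat", seed=2, jitter=False)


def make_frame(
    pulse_index=1,
    time_s=0.0,
    pressure=0.2,
    harmonic=0.0,
    ultra=0.0,
    h4=0.0,
    broadband=0.0,
):
    """AEFrame with constant harmonic/ultra-harmonic levels."""
    if np.isscalar(harmonic):
        harmonic = (float(harmonic),) * 7
    if np.isscalar(ultra):
        ultra = (float(ultra),) * 7
    return AEFrame(
        pulse_index=pulse_index,
        time_s=time_s,
        pressure_mpa=pressure,
        harmonic_db=tuple(harmonic),
        ultraharmonic_db=tuple(ultra),
        h4_db=h4,
        broadband_db=broadband,
        is_event=detect_broadband(broadband),
    )


@pytest.fixture
def frame_factory():
    return make_frame


def make_record(frames, subject=None, protocol=None, label="test", seed=0):
    """SonicationRecord wrapping hand-built frames (phase 'active')."""
    from fusctl.simulate import PulseLog, SonicationRecord

    record = SonicationRecord(
        protocol=protocol or SonicationProtocol(),
        subject=subject or SubjectModel.default(seed=seed, jitter=False),
        controller_label=label,
        seed=seed,
    )
    for f in frames:
        record.pulses.append(
            PulseLog(frame=f, phase="active", prediction=float("nan"), safety_action="none")
        )
    return record


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def training_records_small():
    """Small training corpus shared by predictor/controller tests."""
    return generate_training_records(60, seed=7)


@pytest.fixture(scope="session")
def trained_model_small(training_records_small):
    model, m_train, m_test, balanced, test = train_default_predictor(
        training_records_small, TrainConfig(epochs=200, seed=7, n_restarts=3)
    )
    return model
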