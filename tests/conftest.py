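import numpy as np
import pytest

from pugraft.config import TABLE_COEFFICIENTS
from pugraft.datamodel import MooneyRivlinParams, UniaxialCurve
from pugraft.graftsim import physiological_waveform


@pytest.fixture(scope="session")
def reference_params():
    """The four hydrated-composition coefficient triples, body temperature."""
    return {
        label: MooneyRivlinParams(*coeffs, temperature=310.15)
        for label, coeffs in TABLE_COEFFICIENTS.items()
    }


@pytest.fixture(scope="session")
def study_waveform():
    """180/40 mmHg extremes, 10 mmHg sinusoid amplitude, 1 Hz."""
    return physiological_waveform(180.0, 40.0, 10.0, omega=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def make_curve(strain, stress, label="5-90-5", state="hydrated", sid="s1"):
    return UniaxialCurve(
        specimen_id=sid,
        composition_label=label,
        hydration_state=state,
        strain_eng=np.asarray(strain, float),
        stress_eng=np.asarray(stress, float),
    )


@pytest.fixture(scope="session")
def curve_factory():
    return make_curve
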