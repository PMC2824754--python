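import numpy as np
import pytest

from swaybayes import AttributionParams, StimulusSpec, peak_velocity

#: (sigma_c2, alpha) fitted to the three healthy datasets
HEALTHY_PARAMS = [(0.34, 1.32), (0.37, 1.28), (0.33, 1.03)]
#: (sigma_c2, alpha) fitted to the two vestibular-loss patient datasets
PATIENT_PARAMS = [(0.46, 1.7), (0.524, 1.85)]

STUDY_AMPLITUDES = (1.0, 3.0, 25.0, 100.0, 150.0)


@pytest.fixture(scope="session")
def study_velocities():
    """Scene peak velocities of the five stimulus amplitudes at 0.2 Hz (cm/s)."""
    return np.array(
        [peak_velocity(StimulusSpec(frequency=0.2, amplitude=a)) for a in STUDY_AMPLITUDES]
    )


@pytest.fixture(scope="session")
def healthy_attribution_params():
    return [AttributionParams(sigma_c2=s2, alpha=a) for s2, a in HEALTHY_PARAMS]


@pytest.fixture(scope="session")
def patient_attribution_params():
    return [AttributionParams(sigma_c2=s2, alpha=a) for s2, a in PATIENT_PARAMS]
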