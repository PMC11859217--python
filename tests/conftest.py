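import numpy as np
import pytest

from comboratio import data, pk


#: the study's sampling grid (hours)
SAMPLING_TIMES = (0.17, 0.5, 1.0, 1.5, 4.0, 7.0, 12.0, 24.0)


@pytest.fixture(scope="session")
def sampling_times():
    return np.array(SAMPLING_TIMES)


@pytest.fixture(scope="session")
def cynanchum_table():
    return data.load_fixture("cynanchum_augmented")


def noiseless_profile(fit: pk.PKFit, times=SAMPLING_TIMES):
    return [
        pk.ProfilePoint(time=float(t), concentration=float(pk.predict_concentration(fit, t)))
        for t in times
    ]
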