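import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from nirsmusic import synthetic as syn
from nirsmusic import features as feat
from nirsmusic.core import Recording, default_montage, default_roiset

FS = 8.9286
STIM_DURATION = 180.0


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def roiset(montage):
    return default_roiset(montage)


@pytest.fixture(scope="session")
def audio180():
    """One 3-min synthetic music excerpt shared across the session."""
    return syn.gen_audio(STIM_DURATION, seed=11)


@pytest.fixture(scope="session")
def features180(audio180):
    return feat.extract_features(audio180)


@pytest.fixture(scope="session")
def regressors180(features180, montage):
    """All 24 regressors on the fNIRS clock of a 3-min stimulus segment."""
    n = int(round(STIM_DURATION * FS))
    probe = Recording(data=np.zeros((n, montage.n_channels)), sampling_rate=FS)
    return [feat.make_regressor(s, probe) for s in features180]


@pytest.fixture(scope="session")
def rms_regressor(regressors180):
    return next(r for r in regressors180 if r.feature_name == "rms")
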