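import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from sharewave.montage import build_default_montage
from sharewave.synthdata import EpochSet

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


def make_epochs(data, fs=600.0, t0=-0.5, montage=None, channels=None,
                condition=None, rating=None, rt=None, subject=None):
    """Assemble an EpochSet around a raw (trials, channels, samples) array."""
    montage = montage or build_default_montage()
    n_t, n_c, _ = data.shape
    channels = channels or montage.analysis_channels[:n_c]
    return EpochSet(
        data=np.asarray(data, dtype=float), fs=fs, t0=t0, montage=montage,
        channels=tuple(channels),
        condition=np.asarray(condition) if condition is not None
        else np.array(["share"] * n_t),
        rating=np.asarray(rating, dtype=float) if rating is not None
        else np.full(n_t, 0.5),
        rt=np.asarray(rt, dtype=float) if rt is not None
        else np.full(n_t, 0.5),
        subject=np.asarray(subject) if subject is not None
        else np.zeros(n_t, dtype=int),
    )


@pytest.fixture
def epoch_factory():
    return make_epochs
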