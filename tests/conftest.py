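import numpy as np
import pytest

from snorevol.io import AudioRecording
from snorevol.preprocess import Clip, preprocess
from snorevol import synthetic


RATE = 5000.0


def as_clip(samples: np.ndarray, rate: float = RATE, index: int = 0) -> Clip:
    n = len(samples)
    return Clip(
        index=index,
        samples=samples,
        rate=rate,
        start_s=0.0,
        end_s=n / rate,
    )


def preprocessed_minute(samples: np.ndarray, rate: float = RATE) -> Clip:
    """Run a raw synthetic minute through the standard preprocessing chain."""
    return preprocess(AudioRecording(samples, rate))[0]


@pytest.fixture(scope="session")
def normal_clip() -> Clip:
    return preprocessed_minute(synthetic.gen_normal_minute(11, RATE))


@pytest.fixture(scope="session")
def simple_snore_clip() -> Clip:
    return preprocessed_minute(synthetic.gen_simple_snore_minute(12, RATE))


@pytest.fixture(scope="session")
def apneic_snore_clip() -> Clip:
    return preprocessed_minute(
        synthetic.gen_apneic_snore_minute(13, RATE, pause_s=12.0)
    )


@pytest.fixture(scope="session")
def uncertain_clip() -> Clip:
    return preprocessed_minute(synthetic.gen_uncertain_minute(14, RATE))
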