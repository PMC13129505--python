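import numpy as np
import pytest

from benage.preprocess import HemoRecording


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_hemo(hbo, hbr=None, fs=2000 / 300, qc=None, subject_id="s1"):
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    if hbr is None:
        hbr = -0.4 * hbo
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    return HemoRecording(
        subject_id=subject_id, hbo=hbo, hbr=hbr, hbt=hbo + hbr, fs=fs, qc_mask=qc
    )
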