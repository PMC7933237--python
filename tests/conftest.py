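import numpy as np
import pytest

from ecgtl import GenParams, RhythmClass, generate_upstream_corpus, render_beat_train


@pytest.fixture(scope="session")
def small_corpus():
    """12 patients x 2 segments x 30 s at 250 Hz."""
    return generate_upstream_corpus(12, 2, 30.0, seed=1234)


@pytest.fixture(scope="session")
def clean_params():
    """Generator parameters without ectopy or additive noise."""
    return GenParams(pac_rate=0.0, pvc_rate=0.0, aberration_rate=0.0,
                     baseline_noise_amp=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def nsr_recording(clean_params):
    """Jitter-free 75-BPM sinus recording, 60 s."""
    import dataclasses
    p = dataclasses.replace(clean_params, nsr_ibi_mean=0.8, nsr_ibi_jitter=0.0)
    return render_beat_train([(RhythmClass.NSR, 60.0)], p, fs=250.0,
                             rng=np.random.default_rng(5))
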