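import logging

import numpy as np
import pytest

from motionloc.preprocess import denoise_recording, segment
from motionloc.synthetic import ClassSpec, SynthSpec, gen_dataset

logging.getLogger("motionloc").setLevel(logging.WARNING)


def make_windows(class_names, stream, count, seed, noise_sd=0.05, inertial=None, **spec_kw):
    """Generate, denoise and segment a small labeled dataset."""
    classes = tuple(
        ClassSpec(
            name=name,
            stream=stream,
            count=count,
            inertial=None if inertial is None else inertial[i],
        )
        for i, name in enumerate(class_names)
    )
    spec = SynthSpec(classes=classes, noise_sd=noise_sd, seed=seed, **spec_kw)
    windows = []
    for rec in gen_dataset(spec):
        windows.extend(segment(denoise_recording(rec), stream=stream))
    return windows


@pytest.fixture(scope="session")
def physical_windows():
    """Four separable physical classes, 5 recordings (55 windows) each."""
    return make_windows(("sit", "stand", "walk", "run"), "physical", count=5, seed=11)


@pytest.fixture(scope="session")
def localization_windows():
    """Three localization contexts with GPS and audio, 4 recordings each."""
    return make_windows(("indoor", "outdoor", "vehicle"), "localization", count=4, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
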