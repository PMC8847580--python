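"""Shared fixtures: tiny window parameters, a micro synthetic cohort, and a
session-scoped trained micro-model so authentication/evaluation tests don't
retrain per test."""

import numpy as np
import pytest

from eegfp.fingerprint_model import (
    ClassifierConfig,
    build_classifier,
    split_fingerprint,
    train_classifier,
)
from eegfp.preprocess import WindowParams, build_input_array
from eegfp.signal_io import EegRecording
from eegfp.synthetic_data import CohortSpec, generate_cohort, sessions_of

# micro windowing: gamma = (8-1)*4 + 32 = 60 samples
TINY_PARAMS = WindowParams(T=32, delta=4, eta=8, Delta=64)

# slightly larger profile for tests that need the classifier to actually
# learn a spectral signature: gamma = (16-1)*4 + 64 = 124 samples
LEARN_PARAMS = WindowParams(T=64, delta=4, eta=16, Delta=32)

TINY_MODEL_CFG = dict(
    conv_blocks=((4, (3, 3)), (8, (3, 3))),
    dense_hidden_size=16,
    epochs=4,
    learning_rate=1e-3,
    batch_size=16,
    optimizer_name="rmsprop",
)


@pytest.fixture(scope="session")
def tiny_params() -> WindowParams:
    return TINY_PARAMS


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 2 sessions, 2 channels, 4 s at 160 Hz."""
    spec = CohortSpec(
        n_subjects=3, n_channels=2, duration_s=4.0, sample_rate_hz=160.0,
        seed=123, noise_sd=0.05,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_trained(tiny_cohort):
    """(model, fingerprint_function, channels, params) trained on the micro
    cohort's first sessions."""
    subjects = sorted({r.subject_id for r in tiny_cohort})
    channels = tiny_cohort[0].channel_names
    xs, ys = [], []
    for i, sid in enumerate(subjects):
        rec = sessions_of(tiny_cohort, sid)[0]
        x, _ = build_input_array(rec, channels, TINY_PARAMS, orthogonalize_flag=True)
        xs.append(x)
        ys.append(np.full(x.shape[0], i))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    config = ClassifierConfig(n_classes=len(subjects), seed=7, **TINY_MODEL_CFG)
    model = build_classifier(config, x.shape[1:])
    train_classifier(model, x, y, config)
    return model, split_fingerprint(model), channels, TINY_PARAMS


@pytest.fixture()
def two_channel_recording() -> EegRecording:
    rng = np.random.default_rng(5)
    return EegRecording(
        subject_id="fixture",
        sample_rate_hz=160.0,
        channel_names=["Oz", "T7"],
        data=rng.normal(size=(2, 800)),
    )
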