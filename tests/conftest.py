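"""Shared fixtures.

The heavyweight fixtures (labelled corpora and trained students) are
session-scoped and lazy, so only the tests that exercise the distillation
pipeline pay for them, and every test that needs a given student shares
one training run.
"""

import numpy as np
import pytest

from phonmeter.frontend import AudioSignal, design_bands
from phonmeter.teacher import Teacher
from phonmeter.soundgen import build_corpus, standard_manifest
from phonmeter.dnn import TrainConfig, train

# the study conditions for the desk-scale distillation checks
CORPUS_ROWS = 30000
SPEECH_ROWS = 12000
TRAIN_EPOCHS = 300
TRAIN_BATCH = 128


@pytest.fixture(scope="session")
def bands():
    return design_bands()


@pytest.fixture(scope="session")
def teacher(bands):
    t = Teacher(bands)
    t._build_calibration()
    return t


def tone_signal(freq=1000.0, level_db=60.0, duration=1.0, calibration=94.0):
    n = np.arange(int(duration * 16000))
    amp = np.sqrt(2.0) * 10.0 ** ((level_db - calibration) / 20.0)
    return AudioSignal(amp * np.sin(2.0 * np.pi * freq * n / 16000))


@pytest.fixture(scope="session")
def tones_noises_corpus(teacher):
    manifest = standard_manifest("tones_noises", CORPUS_ROWS, seed=101)
    return build_corpus(manifest, teacher)


@pytest.fixture(scope="session")
def mixed_corpus(teacher):
    manifest = standard_manifest("mixed", CORPUS_ROWS, seed=202)
    return build_corpus(manifest, teacher)


@pytest.fixture(scope="session")
def speech_corpus(teacher):
    manifest = standard_manifest("speech", SPEECH_ROWS, seed=303)
    return build_corpus(manifest, teacher)


def _train_student(dataset, seed):
    cfg = TrainConfig(
        epochs=TRAIN_EPOCHS, batch_size=TRAIN_BATCH, seed=seed
    )
    params, history = train(dataset, cfg)
    return params, history


@pytest.fixture(scope="session")
def tones_noises_student(tones_noises_corpus):
    return _train_student(tones_noises_corpus, seed=7)


@pytest.fixture(scope="session")
def mixed_student(mixed_corpus):
    return _train_student(mixed_corpus, seed=7)


@pytest.fixture(scope="session")
def speech_student(speech_corpus):
    return _train_student(speech_corpus, seed=7)
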