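"""Shared fixtures: tiny protocol configs and synthetic feature sets.

Everything is generated at test time; there are no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from emgdecode import preprocess, synthgen


@pytest.fixture(scope="session")
def tiny_config() -> synthgen.ProtocolConfig:
    """Micro-scale protocol: 2 subjects, 4 classes, 2 x 0.5-s repetitions.

    0.5 s at 4 kHz = 2000 rows = 8 windows per repetition, so every class
    has 16 windows per subject — enough for stratified 10-fold splits while
    staying fast.
    """
    return synthgen.ProtocolConfig(n_subjects=2, n_classes=4, n_reps=2,
                                   duration=0.5)


@pytest.fixture(scope="session")
def tiny_features(tiny_config):
    """Feature matrices for subject 1 of the micro-scale database."""
    profile = synthgen.default_profile(11, tiny_config.n_classes,
                                       tiny_config.n_channels)
    windows = []
    for label in range(1, tiny_config.n_classes + 1):
        for rep in range(tiny_config.n_reps):
            data = synthgen.generate_repetition(
                profile, label, tiny_config, seed=1000 + 17 * label + rep)
            labeled = np.column_stack(
                [data, np.full(len(data), float(label))])
            windows.extend(preprocess.make_windows(
                labeled, tiny_config.window_len))
    X, y = preprocess.feature_matrix(windows)
    return X, y


def gaussian_blobs(n_classes=3, n_per_class=40, d=5, separation=6.0,
                   seed=0, cov_scale=None):
    """Well-separated spherical Gaussian classes for classifier tests."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, separation, size=(n_classes, d))
    X, y = [], []
    for k in range(n_classes):
        scale = 1.0 if cov_scale is None else cov_scale[k]
        X.append(means[k] + scale * rng.standard_normal((n_per_class, d)))
        y.append(np.full(n_per_class, k + 1, dtype=int))
    return np.concatenate(X), np.concatenate(y)


@pytest.fixture
def blobs():
    return gaussian_blobs()
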