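import numpy as np
import pytest

import emorec as er


@pytest.fixture(scope="session")
def training_epochs():
    """30 labelled epochs per class under the default spectral fixtures.

    One 45 s recording per class, cut into 1.5 s epochs (45 / 1.5 = 30).
    """
    epochs = []
    for i, label in enumerate(er.EmotionLabel):
        rec = er.generate_recording(label, 45, seed=100 + i)
        epochs.extend(er.segment(rec))
    return epochs


@pytest.fixture(scope="session")
def hjorth14_training_set(training_epochs):
    X, labels, names = er.extract_features(training_epochs, family="hjorth14")
    return X, labels, names


@pytest.fixture(scope="session")
def trained_model(hjorth14_training_set):
    X, labels, _ = hjorth14_training_set
    return er.train(X, labels, method="svm", seed=0, feature_family="hjorth14")


def band_power_fraction(rec, low, high, channels, total=(0.5, 30.0)):
    """Welch-based band-power fraction oracle, independent of the filter bank."""
    from scipy.signal import welch

    idx = [rec.montage.index(c) for c in channels]
    freqs, psd = welch(rec.data[idx], fs=rec.sampling_rate, nperseg=256)
    denom = psd[:, (freqs >= total[0]) & (freqs <= total[1])].sum()
    return psd[:, (freqs >= low) & (freqs <= high)].sum() / denom


def fft_power_ratio(filtered, original, sampling_rate=None):
    """Mean-square power ratio on the central 80% of the signals."""
    filtered = np.asarray(filtered, dtype=float)
    original = np.asarray(original, dtype=float)
    n = original.size
    core = slice(n // 10, n - n // 10)
    return float(np.mean(filtered[core] ** 2) / np.mean(original[core] ** 2))
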