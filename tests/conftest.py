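import numpy as np
import pytest

from neoecg import SyntheticSpec, generate_ecg


@pytest.fixture(scope="session")
def clean_10s():
    """Clean 10 s synthetic neonatal ECG at 150 bpm, 250 Hz, with truth."""
    return generate_ecg(SyntheticSpec(duration=10.0, seed=42))


@pytest.fixture(scope="session")
def clean_20s():
    return generate_ecg(SyntheticSpec(duration=20.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def match_counts(detected_times, true_times, fs, tol_samples=2):
    """(matched, false_positives) with a +/- tol_samples window."""
    detected_times = np.asarray(detected_times)
    true_times = np.asarray(true_times)
    matched = sum(
        bool(detected_times.size
             and np.min(np.abs(detected_times - t)) * fs <= tol_samples)
        for t in true_times)
    fp = sum(
        bool(true_times.size
             and np.min(np.abs(true_times - d)) * fs > tol_samples)
        for d in detected_times)
    return matched, fp
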