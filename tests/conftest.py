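import numpy as np
import pytest

from phtremor import ExperimentConfig, SessionTruth, default_atlas


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture()
def config():
    return ExperimentConfig(n_animals=1)


@pytest.fixture()
def truth():
    return SessionTruth(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def dft_amplitude_oracle(segment: np.ndarray, rate_hz: float):
    """Independent brute-force DFT amplitude spectrum (Hann windowed).

    O(n^2) explicit sum, periodic Hann written from its cosine
    definition; single-sided 2/N convention (1/N at DC and Nyquist).
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    k = np.arange(n)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / n))
    xw = x * w
    n_bins = n // 2 + 1
    freqs = np.arange(n_bins) * rate_hz / n
    amp = np.empty(n_bins)
    j = np.arange(n)
    for b in range(n_bins):
        c = np.exp(-2j * np.pi * j * b / n)
        amp[b] = abs(np.sum(xw * c)) * 2.0 / n
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    return freqs, amp


def bh_oracle(pvals: np.ndarray, q: float) -> np.ndarray:
    """Exhaustive Benjamini-Hochberg step-up: for each candidate rank k,
    check p_(k) <= k q / m; reject everything at or below the largest
    passing order statistic."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    passing = [k for k in range(1, m + 1) if sorted_p[k - 1] <= k * q / m]
    reject = np.zeros(m, dtype=bool)
    if passing:
        kmax = max(passing)
        reject[order[:kmax]] = True
    return reject
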