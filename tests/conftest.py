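import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_power_spectrum(x, rate_hz):
    """O(N^2) direct DFT squared-magnitude oracle, one-sided.

    Independent of any FFT routine: evaluates the transform sum term by term.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_bins = n // 2 + 1
    k = np.arange(n)
    powers = np.empty(n_bins)
    for j in range(n_bins):
        ang = -2.0 * np.pi * j * k / n
        re = float(x @ np.cos(ang))
        im = float(x @ np.sin(ang))
        powers[j] = re * re + im * im
    freqs = np.arange(n_bins) * rate_hz / n
    return freqs, powers
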