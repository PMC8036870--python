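import numpy as np
import pytest

import respicam as rc


@pytest.fixture(scope="session")
def ctx() -> rc.SpectralContext:
    return rc.SpectralContext()


@pytest.fixture(scope="session")
def still_recording():
    """A small still scene breathing at 42 BPM, reused by several suites."""
    spec = rc.SceneSpec(
        shape=(16, 24),
        duration_s=20.0,
        noise_sigma=0.05,
        cluster=rc.ClusterSpec(region=(5, 11, 8, 16), rr_bpm=42.0, amplitude=1.0, edge_step=4.0),
        seed=11,
    )
    return rc.generate(spec)


def naive_half_spectrum(series: np.ndarray, nz: int) -> np.ndarray:
    """O(N * Nz) DFT-summation oracle: Hanning window, zero-pad, |DFT| half grid.

    Independent of numpy's FFT path (explicit complex-exponential sums).
    """
    x = np.asarray(series, float) * np.hanning(len(series))
    n = np.arange(len(x))
    k = np.arange(nz // 2)
    return np.abs(np.exp(-2j * np.pi * np.outer(k, n) / nz) @ x)
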