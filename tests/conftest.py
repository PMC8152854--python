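import numpy as np
import pytest

from kindleictal.signal_io import Trace


@pytest.fixture
def tone_trace():
    """Factory for single- or multi-tone test traces."""

    def make(freqs, fs=1000.0, duration=4.0, amps=None, phases=None):
        t = np.arange(int(duration * fs)) / fs
        freqs = np.atleast_1d(freqs).astype(float)
        amps = np.ones_like(freqs) if amps is None else np.atleast_1d(amps)
        phases = np.zeros_like(freqs) if phases is None else np.atleast_1d(phases)
        x = sum(
            a * np.cos(2 * np.pi * f * t + p) for f, a, p in zip(freqs, amps, phases)
        )
        return Trace(x, fs)

    return make
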