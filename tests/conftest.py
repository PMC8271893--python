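"""Shared fixtures and small signal builders for the test suite."""

import numpy as np
import pytest

from erpsign.epochs import ErpEpoch


def bump_trace(time_ms, bumps):
    """Sum of Gaussian bumps; ``bumps`` is [(latency_ms, amplitude, width_ms)]."""
    t = np.asarray(time_ms, dtype=float)
    x = np.zeros_like(t)
    for lat, amp, width in bumps:
        x += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
    return x


def bump_epoch(bumps, span=(-1000.0, 2000.0), rate=1000.0, **labels):
    """An epoch whose amplitude is a sum of Gaussian bumps."""
    step = 1000.0 / rate
    n = int(round((span[1] - span[0]) / step))
    t = span[0] + step * np.arange(n)
    return ErpEpoch(time_ms=t, amplitude_uV=bump_trace(t, bumps),
                    sample_rate_hz=rate, **labels)


@pytest.fixture
def make_bump_epoch():
    return bump_epoch


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
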