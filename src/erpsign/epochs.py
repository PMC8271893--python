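"""Stimulus-locked epoch containers.

An *epoch* is a fixed window of EEG voltage around one stimulus onset,
here -1 s to +2 s with onset at time 0.  Single-channel epochs
(:class:`ErpEpoch`) are the unit the rest of the pipeline operates on;
:class:`MultichannelEpoch` exists so a region-of-interest average over
several scalp electrodes can be collapsed into one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ErpEpoch", "MultichannelEpoch"]


def _check_time_axis(time_ms: np.ndarray, sample_rate_hz: float) -> None:
    if time_ms.ndim != 1 or time_ms.size < 2:
        raise ValueError("time axis must be a 1-d vector with at least 2 samples")
    if sample_rate_hz <= 0:
        raise ValueError(f"sample_rate_hz must be positive, got {sample_rate_hz}")
    step = 1000.0 / sample_rate_hz
    if not np.allclose(np.diff(time_ms), step, rtol=1e-6, atol=1e-6):
        raise ValueError("time axis must be uniformly sampled at sample_rate_hz")
    if not (time_ms[0] <= 0.0 <= time_ms[-1]):
        raise ValueError("stimulus onset (t=0) must lie inside the epoch span")


@dataclass
class ErpEpoch:
    """One stimulus-locked single-channel trace.

    Parameters
    ----------
    time_ms
        Uniformly sampled time axis in milliseconds relative to stimulus
        onset; onset (0) must lie inside the span.
    amplitude_uV
        Voltage at each time point, microvolts.
    sample_rate_hz
        Sampling rate consistent with ``time_ms``.
    subject_id, group, condition, shape
        Trial labels; ``group`` is ``"elderly"``/``"youth"``, ``condition``
        is ``"correct"``/``"incorrect"``, ``shape`` the traffic-sign shape.
    """

    time_ms: np.ndarray
    amplitude_uV: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""
    group: str = ""
    condition: str = ""
    shape: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.amplitude_uV = np.asarray(self.amplitude_uV, dtype=float)
        _check_time_axis(self.time_ms, self.sample_rate_hz)
        if self.amplitude_uV.shape != self.time_ms.shape:
            raise ValueError("amplitude_uV and time_ms must have the same length")

    @property
    def n_samples(self) -> int:
        return self.time_ms.size

    def index_of(self, t_ms: float) -> int:
        """Index of the sample nearest to time ``t_ms``."""
        i = int(round((t_ms - self.time_ms[0]) * self.sample_rate_hz / 1000.0))
        if not 0 <= i < self.n_samples:
            raise ValueError(f"time {t_ms} ms outside epoch span "
                             f"[{self.time_ms[0]}, {self.time_ms[-1]}] ms")
        return i

    def with_amplitude(self, amplitude_uV: np.ndarray) -> "ErpEpoch":
        """Copy of this epoch with a new amplitude vector (labels kept)."""
        return replace(self, amplitude_uV=np.asarray(amplitude_uV, dtype=float))


@dataclass
class MultichannelEpoch:
    """A stimulus-locked epoch recorded on several named channels.

    ``data`` is ``(n_channels, n_samples)``; row *i* belongs to
    ``channel_names[i]``.
    """

    time_ms: np.ndarray
    data: np.ndarray
    channel_names: Sequence[str]
    sample_rate_hz: float
    subject_id: str = ""
    group: str = ""
    condition: str = ""
    shape: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = list(self.channel_names)
        _check_time_axis(self.time_ms, self.sample_rate_hz)
        if self.data.shape != (len(self.channel_names), self.time_ms.size):
            raise ValueError("data must be (n_channels, n_samples) matching "
                             "channel_names and time_ms")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
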