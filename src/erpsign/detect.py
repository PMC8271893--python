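"""Automated N200/P300/N400/P600 latency detection.

The detector walks the averaged trace component by component:

* **N200** — most negative interior local minimum in 150–350 ms (falling
  back to the range minimum when the trace has no interior dip there).
* **P300** — largest interior local maximum in 250–500 ms occurring
  *after* the N200.  When no acceptable maximum exists there — which
  happens when the N200 itself fell outside the textbook range — the
  search is re-anchored to the N200 using a fixed gap time (FGT) of
  250 ms and repeated inside ``n200 + 250 ± halfwidth`` ms; as a last
  resort the global maximum of that window is taken.  The result is
  flagged ``via_fgt`` when the fallback fired.
* **N400 / P600** — constrained to start after the previously detected
  component (the textbook ranges overlap), otherwise analogous.

Feature extraction for the classifiers cuts a 1 s window starting at the
detected N200 and linearly resamples it to a fixed number of points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .epochs import ErpEpoch

__all__ = [
    "DetectionConfig",
    "ComponentLatencies",
    "FeatureWindow",
    "detect_n200",
    "detect_p300",
    "detect_n400",
    "detect_p600",
    "detect_components",
    "extract_feature_window",
    "resample_features",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Search ranges (ms) and fixed-gap-time parameters.

    ``prominence_uV`` is the minimum peak prominence for a local maximum
    to count as an "appropriate" P300 candidate; 0 accepts any interior
    local maximum.
    """

    n200_range_ms: tuple[float, float] = (150.0, 350.0)
    p300_range_ms: tuple[float, float] = (250.0, 500.0)
    n400_range_ms: tuple[float, float] = (250.0, 600.0)
    p600_range_ms: tuple[float, float] = (500.0, 800.0)
    fgt_ms: float = 250.0
    fgt_halfwidth_ms: float = 100.0
    prominence_uV: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n200_range_ms", "p300_range_ms",
                     "n400_range_ms", "p600_range_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing interval")
        if self.fgt_ms <= 0:
            raise ValueError("fgt_ms must be positive")
        if self.fgt_halfwidth_ms <= 0:
            raise ValueError("fgt_halfwidth_ms must be positive")
        if self.prominence_uV < 0:
            raise ValueError("prominence_uV must be non-negative")


@dataclass
class ComponentLatencies:
    """Detected component times (ms) for one averaged trace."""

    n200_ms: Optional[float] = None
    p300_ms: Optional[float] = None
    n400_ms: Optional[float] = None
    p600_ms: Optional[float] = None
    p300_via_fgt: bool = False
    variant_tag: str = ""

    def as_dict(self) -> dict[str, Optional[float]]:
        return {"N200": self.n200_ms, "P300": self.p300_ms,
                "N400": self.n400_ms, "P600": self.p600_ms}


def _slice_range(epoch: ErpEpoch, lo_ms: float, hi_ms: float,
                 what: str) -> tuple[np.ndarray, np.ndarray]:
    t = epoch.time_ms
    if lo_ms < t[0] or hi_ms > t[-1]:
        raise ValueError(f"{what} search range [{lo_ms}, {hi_ms}] ms lies "
                         f"outside the epoch span [{t[0]}, {t[-1]}] ms")
    mask = (t >= lo_ms - 1e-9) & (t <= hi_ms + 1e-9)
    return t[mask], epoch.amplitude_uV[mask]


def _interior_extrema(x: np.ndarray, minima: bool,
                      prominence: float = 0.0) -> np.ndarray:
    """Indices of interior local minima/maxima (prominence-filtered)."""
    prom = prominence if prominence > 0 else None
    idx, _ = sps.find_peaks(-x if minima else x, prominence=prom)
    return idx


def _pick(t: np.ndarray, x: np.ndarray, idx: np.ndarray,
          minima: bool) -> float:
    """Most extreme candidate; ties broken by earliest time."""
    vals = x[idx]
    best = int(np.argmin(vals) if minima else np.argmax(vals))
    return float(t[idx[best]])


def detect_n200(epoch: ErpEpoch, config: DetectionConfig = DetectionConfig()
                ) -> float:
    """Latency of the N200: deepest interior dip in the 150–350 ms range,
    or the range minimum when the trace has no interior dip there."""
    t, x = _slice_range(epoch, *config.n200_range_ms, what="N200")
    idx = _interior_extrema(x, minima=True)
    if idx.size:
        return _pick(t, x, idx, minima=True)
    return float(t[int(np.argmin(x))])


def detect_p300(epoch: ErpEpoch, n200_ms: float,
                config: DetectionConfig = DetectionConfig()
                ) -> tuple[float, bool]:
    """Latency of the P300 and whether the fixed-gap-time fallback fired.

    Stage 1 searches the textbook 250–500 ms range for the largest
    interior local maximum after the N200.  Stage 2 (``via_fgt=True``)
    re-anchors the search to ``n200 + fgt ± halfwidth`` and finally falls
    back to the global maximum of that window.
    """
    t, x = _slice_range(epoch, *config.p300_range_ms, what="P300")
    idx = _interior_extrema(x, minima=False, prominence=config.prominence_uV)
    idx = idx[t[idx] > n200_ms]
    if idx.size:
        return _pick(t, x, idx, minima=False), False

    centre = n200_ms + config.fgt_ms
    lo = centre - config.fgt_halfwidth_ms
    hi = centre + config.fgt_halfwidth_ms
    if hi > epoch.time_ms[-1]:
        raise ValueError(f"FGT window [{lo}, {hi}] ms extends beyond the "
                         f"epoch end ({epoch.time_ms[-1]} ms)")
    t2, x2 = _slice_range(epoch, lo, hi, what="P300 FGT")
    idx2 = _interior_extrema(x2, minima=False, prominence=config.prominence_uV)
    if idx2.size:
        return _pick(t2, x2, idx2, minima=False), True
    return float(t2[int(np.argmax(x2))]), True


def detect_n400(epoch: ErpEpoch, p300_ms: float,
                config: DetectionConfig = DetectionConfig()
                ) -> Optional[float]:
    """Latency of the N400 in [max(range start, P300), range end].

    Returns ``None`` when the P300 already lies at or beyond the end of
    the N400 range (empty search range).
    """
    lo = max(config.n400_range_ms[0], p300_ms)
    hi = config.n400_range_ms[1]
    if lo >= hi:
        return None
    t, x = _slice_range(epoch, lo, hi, what="N400")
    idx = _interior_extrema(x, minima=True)
    if idx.size:
        return _pick(t, x, idx, minima=True)
    return float(t[int(np.argmin(x))])


def detect_p600(epoch: ErpEpoch, n400_ms: Optional[float],
                config: DetectionConfig = DetectionConfig()
                ) -> Optional[float]:
    """Latency of the P600 in [max(range start, N400), range end]."""
    lo = config.p600_range_ms[0]
    if n400_ms is not None:
        lo = max(lo, n400_ms)
    hi = config.p600_range_ms[1]
    if lo >= hi:
        return None
    t, x = _slice_range(epoch, lo, hi, what="P600")
    idx = _interior_extrema(x, minima=False)
    if idx.size:
        return _pick(t, x, idx, minima=False)
    return float(t[int(np.argmax(x))])


def detect_components(epoch: ErpEpoch,
                      config: DetectionConfig = DetectionConfig(),
                      variant_tag: str = "") -> ComponentLatencies:
    """Run the full N200 → P300 → N400 → P600 detection chain."""
    n200 = detect_n200(epoch, config)
    p300, via_fgt = detect_p300(epoch, n200, config)
    n400 = detect_n400(epoch, p300, config)
    p600 = detect_p600(epoch, n400, config)
    return ComponentLatencies(n200_ms=n200, p300_ms=p300, n400_ms=n400,
                              p600_ms=p600, p300_via_fgt=via_fgt,
                              variant_tag=variant_tag)


@dataclass
class FeatureWindow:
    """A contiguous segment cut from an epoch (window need not contain 0)."""

    time_ms: np.ndarray
    amplitude_uV: np.ndarray
    sample_rate_hz: float


def extract_feature_window(epoch: ErpEpoch, n200_ms: float,
                           duration_ms: float = 1000.0) -> FeatureWindow:
    """Cut the half-open window ``[n200, n200 + duration)`` from an epoch.

    This is the classifier's observation window: one second of post-N200
    trace containing the whole component complex.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    i0 = epoch.index_of(n200_ms)
    n = int(round(duration_ms * epoch.sample_rate_hz / 1000.0))
    if i0 + n > epoch.n_samples:
        raise ValueError(
            f"epoch ends at {epoch.time_ms[-1]} ms; cannot cut a "
            f"{duration_ms} ms window starting at {n200_ms} ms")
    return FeatureWindow(time_ms=epoch.time_ms[i0:i0 + n].copy(),
                         amplitude_uV=epoch.amplitude_uV[i0:i0 + n].copy(),
                         sample_rate_hz=epoch.sample_rate_hz)


def resample_features(segment: FeatureWindow | np.ndarray,
                      n_points: int = 70) -> np.ndarray:
    """Linearly resample a segment at ``n_points`` evenly spaced times.

    The sample times span the segment inclusively, so
    ``n_points == len(segment)`` reproduces the segment exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if isinstance(segment, FeatureWindow):
        t, x = segment.time_ms, segment.amplitude_uV
    else:
        x = np.asarray(segment, dtype=float)
        t = np.arange(x.size, dtype=float)
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    ti = np.linspace(t[0], t[-1], n_points)
    return np.interp(ti, t, x)
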