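"""Component detection: search ranges, fixed-gap-time fallback, features.

Every detector is also compared against an independent brute-force scan
over the local extrema of the search range.
"""

import numpy as np
import pytest

import erpsign as es
from erpsign.detect import (DetectionConfig, detect_components, detect_n200,
                            detect_n400, detect_p300, detect_p600,
                            extract_feature_window, resample_features)
from conftest import bump_epoch

CFG = DetectionConfig()


# ---------------------------------------------------------------- oracles
# Independent re-implementations of the stated contracts with plain loops.

def _window(ep, lo, hi):
    m = (ep.time_ms >= lo) & (ep.time_ms <= hi)
    return ep.time_ms[m], ep.amplitude_uV[m]


def _strict_minima(x):
    return [i for i in range(1, len(x) - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]


def _strict_maxima(x):
    return [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]


def oracle_n200(ep, cfg=CFG):
    t, x = _window(ep, *cfg.n200_range_ms)
    idx = _strict_minima(x)
    if idx:
        best = min(idx, key=lambda i: (x[i], t[i]))
        return t[best]
    return t[int(np.argmin(x))]


def oracle_p300(ep, n200, cfg=CFG):
    t, x = _window(ep, *cfg.p300_range_ms)
    idx = [i for i in _strict_maxima(x) if t[i] > n200]
    if idx:
        best = max(idx, key=lambda i: (x[i], -t[i]))
        return t[best], False
    t2, x2 = _window(ep, n200 + cfg.fgt_ms - cfg.fgt_halfwidth_ms,
                     n200 + cfg.fgt_ms + cfg.fgt_halfwidth_ms)
    idx2 = _strict_maxima(x2)
    if idx2:
        best = max(idx2, key=lambda i: (x2[i], -t2[i]))
        return t2[best], True
    return t2[int(np.argmax(x2))], True


def oracle_n400(ep, p300, cfg=CFG):
    lo = max(cfg.n400_range_ms[0], p300)
    if lo >= cfg.n400_range_ms[1]:
        return None
    t, x = _window(ep, lo, cfg.n400_range_ms[1])
    idx = _strict_minima(x)
    if idx:
        best = min(idx, key=lambda i: (x[i], t[i]))
        return t[best]
    return t[int(np.argmin(x))]


def oracle_p600(ep, n400, cfg=CFG):
    lo = cfg.p600_range_ms[0] if n400 is None else max(cfg.p600_range_ms[0], n400)
    if lo >= cfg.p600_range_ms[1]:
        return None
    t, x = _window(ep, lo, cfg.p600_range_ms[1])
    idx = _strict_maxima(x)
    if idx:
        best = max(idx, key=lambda i: (x[i], -t[i]))
        return t[best]
    return t[int(np.argmax(x))]


def random_traces(n, seed=20240917):
    """Noisy synthetic traces spanning both groups and conditions."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        grp = ("elderly", "youth")[i % 2]
        cond = ("correct", "incorrect")[(i // 2) % 2]
        cfg = es.default_config(grp, cond, noise_sd_uV=float(rng.uniform(1, 6)))
        out.append(es.make_erp_epoch(cfg, rng=rng))
    return out


# ------------------------------------------------------------------- tests

class TestDetectN200:
    def test_single_negative_bump(self):
        ep = bump_epoch([(250, -5, 20)])
        assert detect_n200(ep, CFG) == 250

    def test_deepest_of_two_dips_wins(self):
        ep = bump_epoch([(180, -2, 10), (300, -5, 10)])
        assert detect_n200(ep, CFG) == 300

    def test_monotone_trace_falls_back_to_range_start(self):
        t = -1000.0 + np.arange(3000.0)
        ep = es.ErpEpoch(time_ms=t, amplitude_uV=0.01 * t,
                         sample_rate_hz=1000.0)
        assert detect_n200(ep, CFG) == 150

    def test_range_outside_epoch_rejected(self):
        ep = bump_epoch([(250, -5, 20)], span=(-100, 300))
        with pytest.raises(ValueError, match="outside the epoch span"):
            detect_n200(ep, CFG)


class TestDetectP300:
    def test_in_range_bump_found_without_fallback(self):
        ep = bump_epoch([(350, 8, 20)])
        assert detect_p300(ep, 230.0, CFG) == (350, False)

    def test_fallback_when_range_is_monotone(self):
        """Strictly rising through 250-500 ms with the true peak at 560:
        the FGT window anchored at N200=330 ([480, 680]) recovers it."""
        t = -1000.0 + np.arange(3000.0)
        ramp = np.where(t > 0, 0.004 * t, 0.0)
        x = ramp + 5.0 * np.exp(-0.5 * ((t - 560) / 25) ** 2)
        ep = es.ErpEpoch(time_ms=t, amplitude_uV=x, sample_rate_hz=1000.0)
        assert _strict_maxima(_window(ep, 250, 500)[1]) == []  # premise
        lat, via_fgt = detect_p300(ep, 330.0, CFG)
        assert via_fgt and abs(lat - 560) <= 1  # apex nudged by the ramp

    def test_maximum_before_n200_ignored(self):
        # only candidate in range sits before the N200 -> fallback fires
        ep = bump_epoch([(260, 8, 5), (530, 4, 15)])
        lat, via_fgt = detect_p300(ep, 280.0, CFG)
        assert via_fgt and lat == 530

    def test_fgt_window_beyond_epoch_rejected(self):
        ep = bump_epoch([(300, -5, 10)], span=(-100, 520))
        with pytest.raises(ValueError, match="FGT window"):
            detect_p300(ep, 340.0, CFG)

    def test_fgt_result_stays_within_guaranteed_band(self):
        """Whenever the fallback fires the latency lies in
        [n200+fgt-halfwidth, n200+fgt+halfwidth] = [n200+150, n200+350]."""
        for ep in random_traces(40, seed=11):
            n200 = detect_n200(ep, CFG)
            lat, via_fgt = detect_p300(ep, n200, CFG)
            if via_fgt:
                assert n200 + 150 <= lat <= n200 + 350


class TestDetectN400P600:
    def test_n400_simple_dip(self):
        ep = bump_epoch([(510, -4, 15)])
        assert detect_n400(ep, 400.0, CFG) == 510

    def test_n400_ignores_dip_before_p300(self):
        ep = bump_epoch([(300, -6, 10), (540, -4, 10)])
        assert detect_n400(ep, 400.0, CFG) == 540

    def test_n400_flat_trace_falls_back_to_range_start(self):
        t = -1000.0 + np.arange(3000.0)
        ep = es.ErpEpoch(time_ms=t, amplitude_uV=np.zeros_like(t),
                         sample_rate_hz=1000.0)
        assert detect_n400(ep, 400.0, CFG) == 400

    def test_n400_absent_when_p300_beyond_range(self):
        ep = bump_epoch([(510, -4, 15)])
        assert detect_n400(ep, 600.0, CFG) is None

    def test_p600_simple_bump(self):
        ep = bump_epoch([(640, 5, 20)])
        assert detect_p600(ep, 530.0, CFG) == 640

    def test_p600_ignores_bump_before_n400(self):
        ep = bump_epoch([(520, 7, 10), (660, 5, 10)])
        assert detect_p600(ep, 530.0, CFG) == 660

    def test_p600_on_noiseless_default_trace(self):
        cfg = es.default_config("elderly", noise_sd_uV=0.0)
        ep = es.make_erp_epoch(cfg, seed=0)
        lat = detect_components(ep, CFG)
        assert lat.p600_ms == 640


class TestDetectorProperties:
    def test_ordering_on_noiseless_defaults(self):
        for grp in ("elderly", "youth"):
            for cond in ("correct", "incorrect"):
                cfg = es.default_config(grp, cond, noise_sd_uV=0.0)
                lat = detect_components(es.make_erp_epoch(cfg, seed=0), CFG)
                assert lat.n200_ms < lat.p300_ms < lat.n400_ms < lat.p600_ms

    def test_oracle_equivalence_on_random_traces(self):
        """Each detector equals an exhaustive local-extrema scan."""
        for ep in random_traces(25):
            n200 = detect_n200(ep, CFG)
            assert n200 == oracle_n200(ep)
            p300, via = detect_p300(ep, n200, CFG)
            assert (p300, via) == oracle_p300(ep, n200)
            n400 = detect_n400(ep, p300, CFG)
            assert n400 == oracle_n400(ep, p300)
            assert detect_p600(ep, n400, CFG) == oracle_p600(ep, n400)


class TestFeatureExtraction:
    def test_window_has_1000_samples_from_n200(self):
        cfg = es.default_config("elderly", noise_sd_uV=0.0)
        ep = es.make_erp_epoch(cfg, seed=0)
        seg = extract_feature_window(ep, 236.0)
        assert seg.amplitude_uV.size == 1000
        assert seg.time_ms[0] == 236.0

    def test_window_values_equal_epoch_slice(self, rng):
        ep = bump_epoch([(400, 8, 30)])
        ep = ep.with_amplitude(ep.amplitude_uV + rng.standard_normal(ep.n_samples))
        seg = extract_feature_window(ep, 250.0)
        i0 = ep.index_of(250.0)
        assert np.array_equal(seg.amplitude_uV, ep.amplitude_uV[i0:i0 + 1000])

    def test_window_start_matches_detected_n200_within_one_sample(self):
        for ep in random_traces(10, seed=5):
            n200 = detect_n200(ep, CFG)
            seg = extract_feature_window(ep, n200)
            assert abs(seg.time_ms[0] - n200) < 1.0

    def test_insufficient_span_rejected(self):
        ep = bump_epoch([(250, -5, 20)], span=(-100, 900))
        with pytest.raises(ValueError, match="window"):
            extract_feature_window(ep, 250.0)


class TestResampleFeatures:
    def test_constant_segment(self):
        assert np.allclose(resample_features(np.full(1000, 3.3), 70), 3.3)

    def test_linear_ramp_resamples_to_even_spacing(self):
        out = resample_features(np.linspace(0, 1, 1000), 70)
        assert np.allclose(out, np.linspace(0, 1, 70))

    def test_identity_when_n_points_equals_length(self, rng):
        x = rng.standard_normal(70)
        assert np.allclose(resample_features(x, 70), x)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_features(np.zeros(100), 1)
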