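"""Synthetic generator: determinism, parameter recovery, trial-log statistics."""

import numpy as np
import pytest

import erpsign as es
from erpsign.synth import (DEFAULT_ERROR_RATES, ErpComponentSpec,
                           SyntheticConfig, default_config, make_dataset,
                           make_erp_epoch, make_trial_log)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(name="N200", latency_ms=236, amplitude_uV=-5, width_ms=0.0),
        dict(name="N200", latency_ms=-10, amplitude_uV=-5, width_ms=20),
        dict(name="N200", latency_ms=236, amplitude_uV=5, width_ms=20),
        dict(name="P300", latency_ms=398, amplitude_uV=-8, width_ms=20),
        dict(name="P123", latency_ms=398, amplitude_uV=8, width_ms=20),
    ])
    def test_invalid_component_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ErpComponentSpec(**kwargs)

    @pytest.mark.parametrize("overrides", [
        dict(sample_rate_hz=0.0),
        dict(noise_sd_uV=-1.0),
        dict(fluctuation_gain_incorrect=0.5),
        dict(p_different=1.5),
        dict(error_rate=-0.1),
        dict(epoch_span_ms=(100.0, 2000.0)),
    ])
    def test_invalid_config_rejected(self, overrides):
        with pytest.raises(ValueError):
            default_config("elderly", **overrides)

    def test_component_order_enforced(self):
        comps = (ErpComponentSpec("N200", 400, -5, 20),
                 ErpComponentSpec("P300", 300, 8, 20))
        with pytest.raises(ValueError):
            SyntheticConfig(group="elderly", components=comps)


class TestMakeErpEpoch:
    @pytest.mark.parametrize("group,condition", [
        ("elderly", "correct"), ("elderly", "incorrect"),
        ("youth", "correct"), ("youth", "incorrect"),
    ])
    def test_noiseless_latencies_recovered_within_one_sample(self, group, condition):
        """With no noise the detector must find each configured component
        latency to within one sample period (the generator/detector loop)."""
        cfg = default_config(group, condition, noise_sd_uV=0.0)
        ep = make_erp_epoch(cfg, seed=0)
        detected = es.detect_components(ep).as_dict()
        shifts = cfg.incorrect_latency_shift_ms
        step = 1000.0 / cfg.sample_rate_hz
        for comp in cfg.components:
            expected = comp.latency_ms
            if condition == "incorrect":
                expected += shifts[comp.name]
            assert abs(detected[comp.name] - expected) <= step

    def test_empty_component_list_gives_zero_trace(self):
        cfg = default_config("elderly", components=(), noise_sd_uV=0.0)
        ep = make_erp_epoch(cfg, seed=0)
        assert np.all(ep.amplitude_uV == 0.0)

    def test_deterministic_given_seed(self):
        cfg = default_config("youth")
        a = make_erp_epoch(cfg, seed=42)
        b = make_erp_epoch(cfg, seed=42)
        c = make_erp_epoch(cfg, seed=43)
        assert np.array_equal(a.amplitude_uV, b.amplitude_uV)
        assert not np.array_equal(a.amplitude_uV, c.amplitude_uV)

    def test_noise_scaled_to_requested_sd_and_gain(self):
        correct = make_erp_epoch(default_config("elderly", components=(),
                                                noise_sd_uV=3.0), seed=5)
        incorrect = make_erp_epoch(default_config(
            "elderly", "incorrect", components=(), noise_sd_uV=3.0,
            fluctuation_gain_incorrect=2.0), seed=5)
        assert correct.amplitude_uV.std() == pytest.approx(3.0, rel=1e-9)
        assert incorrect.amplitude_uV.std() == pytest.approx(6.0, rel=1e-9)

    def test_time_axis_spans_configured_window(self):
        ep = make_erp_epoch(default_config("elderly", noise_sd_uV=0.0), seed=0)
        assert ep.time_ms[0] == -1000.0
        assert ep.time_ms[-1] == 1999.0
        assert ep.n_samples == 3000


class TestMakeTrialLog:
    def test_zero_subjects_gives_empty_log(self):
        assert make_trial_log(default_config("elderly"), 0, seed=0) == []

    def test_trial_count_conservation(self):
        cfg = default_config("youth", n_trials_per_shape=7)
        log = make_trial_log(cfg, 5, seed=1)
        assert len(log) == 5 * 3 * 7

    def test_error_rate_recovered_at_n2000(self):
        """Empirical error rate lands inside the binomial 99% interval
        around the configured rate (n=2000, p=0.2 -> [0.18, 0.22])."""
        cfg = default_config("elderly", error_rate=0.2, n_trials_per_shape=20)
        log = make_trial_log(cfg, 34, seed=7)[:2000]
        rate = np.mean([not t.is_correct for t in log])
        assert 0.18 <= rate <= 0.22

    def test_p_different_fraction_within_binomial_bounds(self):
        cfg = default_config("youth", p_different=0.75)
        log = make_trial_log(cfg, 40, seed=3)
        n = len(log)
        frac = np.mean([t.is_different for t in log])
        assert abs(frac - 0.75) <= 3 * np.sqrt(0.75 * 0.25 / n)

    def test_records_satisfy_correctness_invariant(self):
        # TrialRecord.__post_init__ enforces the invariant; surviving
        # construction means every record is internally consistent.
        log = make_trial_log(default_config("elderly"), 3, seed=0)
        assert any(t.response == "none" for t in log)
        for t in log:
            if t.response == "none":
                assert not t.is_correct and t.response_time_ms is None
            else:
                assert 0 < t.response_time_ms <= 1800.0

    def test_default_error_rates_follow_reference_ratios(self):
        assert DEFAULT_ERROR_RATES["elderly"]["triangle"] == pytest.approx(
            5.0 / 20.2, abs=5e-5)
        assert DEFAULT_ERROR_RATES["youth"]["circle"] == pytest.approx(
            3.2 / 19.7, abs=5e-5)


def _both_conditions(group, **overrides):
    return {(group, cond): default_config(group, cond, **overrides)
            for cond in ("correct", "incorrect")}


class TestMakeDataset:
    def test_one_subject_one_shape_counts(self):
        cfgs = _both_conditions("elderly", shapes=("triangle",))
        bundle = make_dataset(cfgs, 1, seed=0)
        assert len(bundle.trials) == 20
        assert len(bundle.epochs) == 20  # one epoch per trial

    def test_epoch_condition_matches_trial_correctness(self):
        bundle = make_dataset(_both_conditions("youth"), 2, seed=1)
        for trial, epoch in zip(bundle.trials, bundle.epochs):
            assert epoch.subject_id == trial.subject_id
            assert epoch.shape == trial.shape
            assert epoch.condition == ("correct" if trial.is_correct
                                       else "incorrect")

    def test_fixed_seed_reproduces_bundle_exactly(self):
        cfgs = _both_conditions("elderly")
        a = make_dataset(cfgs, 2, seed=9)
        b = make_dataset(cfgs, 2, seed=9)
        assert a.trials == b.trials
        assert all(np.array_equal(x.amplitude_uV, y.amplitude_uV)
                   for x, y in zip(a.epochs, b.epochs))

    def test_duplicate_subject_ids_rejected(self):
        cfgs = _both_conditions("elderly")
        with pytest.raises(ValueError, match="duplicate"):
            make_dataset(cfgs, 2, seed=0,
                         subject_ids={"elderly": ["s1", "s1"]})

    def test_missing_condition_config_rejected(self):
        cfgs = {("elderly", "correct"): default_config("elderly")}
        with pytest.raises(ValueError, match="incorrect"):
            make_dataset(cfgs, 1, seed=0)

    def test_noiseless_group_gap_equals_configured_shift(self):
        """On noiseless data the detected correct-vs-incorrect latency gap
        equals the configured shift exactly (the generator is the oracle)."""
        cfgs = _both_conditions("elderly", noise_sd_uV=0.0)
        bundle = make_dataset(cfgs, 2, seed=0)
        out = {}
        for cond in ("correct", "incorrect"):
            avg = es.average_epochs(bundle.epochs_for(condition=cond))
            out[cond] = es.detect_components(avg).as_dict()
        for comp, shift in es.refdata.GAP_TIMES_MS["elderly"].items():
            assert out["incorrect"][comp] - out["correct"][comp] == \
                pytest.approx(shift, abs=1.0)
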