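"""Synthetic Go/Nogo behavioural logs and ERP epochs.

The generator emulates the statistical structure the downstream analysis
assumes: stimulus-locked traces carrying an N200/P300/N400/P600 complex
(Gaussian bumps of the correct polarity), band-limited background noise,
incorrect-answer traces whose component latencies are shifted by the
group's gap times and whose fluctuation is larger, and behavioural trial
logs with 75 % "different" stimuli and per-shape error rates.

Defaults are the study conditions: component latencies from the group
average rows of the reference latency table (:mod:`erpsign.refdata`),
incorrect-condition shifts equal to the published gap times, per-shape
error rates equal to the reference incorrect/(correct+incorrect) ratios,
20 trials per shape and a 1.8 s response window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .epochs import ErpEpoch
from .preprocess import zero_phase_bandpass
from . import refdata

__all__ = [
    "SHAPES",
    "COMPONENT_ORDER",
    "ErpComponentSpec",
    "SyntheticConfig",
    "TrialRecord",
    "DatasetBundle",
    "default_components",
    "default_config",
    "make_erp_epoch",
    "make_trial_log",
    "make_dataset",
]

SHAPES = refdata.SHAPES
COMPONENT_ORDER = refdata.COMPONENTS

_NEGATIVE = {"N200", "N400"}
_POSITIVE = {"P300", "P600"}

#: Field-typical peak amplitudes (uV) and Gaussian widths (ms) used when a
#: component spec is built from defaults.  Widths are kept narrow enough
#: that neighbouring bumps (closest spacing: 73 ms between the shifted
#: youth P300 and N400) do not displace each other's extrema by more than
#: one sample on a noiseless trace.
DEFAULT_AMPLITUDES_UV = {"N200": -5.0, "P300": 8.0, "N400": -4.0, "P600": 5.0}
DEFAULT_WIDTHS_MS = {"N200": 20.0, "P300": 22.0, "N400": 22.0, "P600": 28.0}

#: Per-shape error rates: reference incorrect/(correct+incorrect) ratios.
DEFAULT_ERROR_RATES = {
    group: {
        shape: round(inc / (corr + inc), 4)
        for shape, (corr, _, inc, _) in refdata.BEHAVIOR_COUNTS[group].items()
    }
    for group in refdata.GROUPS
}


@dataclass(frozen=True)
class ErpComponentSpec:
    """One ERP component modelled as a Gaussian voltage bump.

    ``width_ms`` is the standard deviation of the bump.  Polarity is
    enforced: N200/N400 are negative-going, P300/P600 positive-going.
    """

    name: str
    latency_ms: float
    amplitude_uV: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_ORDER:
            raise ValueError(f"unknown component {self.name!r}")
        if self.latency_ms <= 0:
            raise ValueError(f"{self.name}: latency_ms must be positive")
        if self.width_ms <= 0:
            raise ValueError(f"{self.name}: width_ms must be positive")
        if self.name in _NEGATIVE and self.amplitude_uV >= 0:
            raise ValueError(f"{self.name} must have negative amplitude")
        if self.name in _POSITIVE and self.amplitude_uV <= 0:
            raise ValueError(f"{self.name} must have positive amplitude")


def _check_component_order(components: Sequence[ErpComponentSpec]) -> None:
    by_name = {c.name: c for c in components}
    present = [n for n in COMPONENT_ORDER if n in by_name]
    lats = [by_name[n].latency_ms for n in present]
    if any(b <= a for a, b in zip(lats, lats[1:])):
        raise ValueError("component latencies must increase in the order "
                         "N200 < P300 < N400 < P600")


@dataclass
class SyntheticConfig:
    """Full recipe for one group x condition of synthetic data.

    ``components`` carries the *correct-answer* latencies; when
    ``condition == "incorrect"`` each component is displaced by
    ``incorrect_latency_shift_ms[name]`` and the noise amplitude is
    multiplied by ``fluctuation_gain_incorrect`` (incorrect-answer traces
    fluctuate more in real recordings).  ``error_rate`` may be a single
    probability or a per-shape mapping.
    """

    group: str
    condition: str = "correct"
    components: Sequence[ErpComponentSpec] = ()
    incorrect_latency_shift_ms: Mapping[str, float] = field(default_factory=dict)
    noise_sd_uV: float = 10.0
    noise_band_hz: tuple[float, float] = (4.0, 30.0)
    fluctuation_gain_incorrect: float = 2.0
    sample_rate_hz: float = 1000.0
    epoch_span_ms: tuple[float, float] = (-1000.0, 2000.0)
    shapes: Sequence[str] = SHAPES
    n_trials_per_shape: int = 20
    p_different: float = 0.75
    error_rate: float | Mapping[str, float] = 0.2
    no_response_share: float = 0.2
    response_window_ms: float = 1800.0
    stimulus_duration_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in refdata.GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.condition not in ("correct", "incorrect"):
            raise ValueError(f"unknown condition {self.condition!r}")
        self.components = tuple(self.components)
        _check_component_order(self.components)
        if self.noise_sd_uV < 0:
            raise ValueError("noise_sd_uV must be non-negative")
        if self.fluctuation_gain_incorrect < 1:
            raise ValueError("fluctuation_gain_incorrect must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        start, end = self.epoch_span_ms
        if not start < 0 < end:
            raise ValueError("epoch span must contain stimulus onset: "
                             "start < 0 < end")
        if not 0 <= self.p_different <= 1:
            raise ValueError("p_different must lie in [0, 1]")
        if not 0 <= self.no_response_share <= 1:
            raise ValueError("no_response_share must lie in [0, 1]")
        for shape in self.shapes:
            r = self.error_rate_for(shape)
            if not 0 <= r <= 1:
                raise ValueError(f"error rate for {shape!r} must lie in [0, 1]")
        if self.n_trials_per_shape < 0:
            raise ValueError("n_trials_per_shape must be non-negative")

    def error_rate_for(self, shape: str) -> float:
        if isinstance(self.error_rate, Mapping):
            if shape not in self.error_rate:
                raise ValueError(f"no error rate configured for shape {shape!r}")
            return float(self.error_rate[shape])
        return float(self.error_rate)


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one Go/Nogo trial.

    The task: left-click when the HUD sign differs from the road sign
    ("different", 75 % of trials), right-click when it matches.  A wrong
    click or no response inside the 1.8 s window counts as incorrect.
    """

    subject_id: str
    group: str
    shape: str
    trial_index: int
    is_different: bool
    response: str  # "left" | "right" | "none"
    response_time_ms: float | None
    is_correct: bool

    def __post_init__(self) -> None:
        if self.response not in ("left", "right", "none"):
            raise ValueError(f"invalid response {self.response!r}")
        expected = ((self.is_different and self.response == "left")
                    or (not self.is_different and self.response == "right"))
        if self.is_correct != expected:
            raise ValueError(
                f"inconsistent record for {self.subject_id}/{self.shape}"
                f"#{self.trial_index}: is_correct={self.is_correct} but "
                f"is_different={self.is_different}, response={self.response!r}")
        if self.response == "none" and self.response_time_ms is not None:
            raise ValueError("response='none' cannot carry a response time")


def default_components(group: str) -> tuple[ErpComponentSpec, ...]:
    """Correct-answer component specs built from the reference latency table."""
    lats = refdata.AVG_LATENCIES[(group, "correct")]
    return tuple(
        ErpComponentSpec(name=n, latency_ms=float(lats[n]),
                         amplitude_uV=DEFAULT_AMPLITUDES_UV[n],
                         width_ms=DEFAULT_WIDTHS_MS[n])
        for n in COMPONENT_ORDER
    )


def default_config(group: str, condition: str = "correct",
                   **overrides) -> SyntheticConfig:
    """Study-condition defaults for one group and answer condition."""
    base = dict(
        group=group,
        condition=condition,
        components=default_components(group),
        incorrect_latency_shift_ms=dict(refdata.GAP_TIMES_MS[group]),
        error_rate=dict(DEFAULT_ERROR_RATES[group]),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def _time_axis(config: SyntheticConfig) -> np.ndarray:
    start, end = config.epoch_span_ms
    step = 1000.0 / config.sample_rate_hz
    n = int(round((end - start) / step))
    return start + step * np.arange(n)


def make_erp_epoch(config: SyntheticConfig,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   subject_id: str = "",
                   shape: str = "") -> ErpEpoch:
    """Simulate one stimulus-locked trace.

    The trace is the sum of the configured Gaussian bumps (latencies
    shifted when ``condition == "incorrect"``) plus band-limited white
    noise rescaled to ``noise_sd_uV`` (times the fluctuation gain for
    incorrect trials).  Deterministic given ``(config, seed)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    t = _time_axis(config)
    x = np.zeros_like(t)
    shifts = config.incorrect_latency_shift_ms
    for comp in config.components:
        lat = comp.latency_ms
        if config.condition == "incorrect":
            lat += float(shifts.get(comp.name, 0.0))
        x += comp.amplitude_uV * np.exp(-0.5 * ((t - lat) / comp.width_ms) ** 2)
    sd = config.noise_sd_uV
    if config.condition == "incorrect":
        sd *= config.fluctuation_gain_incorrect
    if sd > 0:
        noise = rng.standard_normal(t.size)
        noise = zero_phase_bandpass(noise, config.noise_band_hz,
                                    order=4, sample_rate_hz=config.sample_rate_hz)
        noise *= sd / noise.std()
        x = x + noise
    return ErpEpoch(time_ms=t, amplitude_uV=x,
                    sample_rate_hz=config.sample_rate_hz,
                    subject_id=subject_id, group=config.group,
                    condition=config.condition, shape=shape)


def _draw_response_time(rng: np.random.Generator, correct: bool,
                        window_ms: float) -> float:
    # correct answers cluster well inside the window; wrong clicks later
    loc, scale = (650.0, 150.0) if correct else (950.0, 250.0)
    return float(np.clip(rng.normal(loc, scale), 200.0, window_ms))


def make_trial_log(config: SyntheticConfig, n_subjects: int,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   subject_ids: Sequence[str] | None = None) -> list[TrialRecord]:
    """Simulate the behavioural log of ``n_subjects`` subjects.

    Each subject answers ``n_trials_per_shape`` trials per shape; stimuli
    are "different" with probability ``p_different``; a trial is incorrect
    with the shape's error rate, and a share ``no_response_share`` of the
    incorrect trials are timeouts (no click) rather than wrong clicks.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if subject_ids is None:
        subject_ids = [f"{config.group}-{i + 1:02d}" for i in range(n_subjects)]
    elif len(subject_ids) != n_subjects:
        raise ValueError("subject_ids must have length n_subjects")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")

    records: list[TrialRecord] = []
    for sid in subject_ids:
        for shape in config.shapes:
            err = config.error_rate_for(shape)
            for k in range(config.n_trials_per_shape):
                is_diff = bool(rng.random() < config.p_different)
                correct = bool(rng.random() >= err)
                right_answer = "left" if is_diff else "right"
                if correct:
                    response = right_answer
                    rt = _draw_response_time(rng, True, config.response_window_ms)
                elif rng.random() < config.no_response_share:
                    response, rt = "none", None
                else:
                    response = "right" if right_answer == "left" else "left"
                    rt = _draw_response_time(rng, False, config.response_window_ms)
                records.append(TrialRecord(
                    subject_id=sid, group=config.group, shape=shape,
                    trial_index=k, is_different=is_diff, response=response,
                    response_time_ms=rt, is_correct=correct))
    return records


@dataclass
class DatasetBundle:
    """Trial log plus one single-trial epoch per trial, ready for analysis."""

    epochs: list[ErpEpoch]
    trials: list[TrialRecord]
    seed: int

    def epochs_for(self, subject_id: str | None = None,
                   group: str | None = None,
                   condition: str | None = None,
                   shape: str | None = None) -> list[ErpEpoch]:
        """Epochs matching every given label."""
        out = []
        for ep in self.epochs:
            if subject_id is not None and ep.subject_id != subject_id:
                continue
            if group is not None and ep.group != group:
                continue
            if condition is not None and ep.condition != condition:
                continue
            if shape is not None and ep.shape != shape:
                continue
            out.append(ep)
        return out


def make_dataset(configs: Mapping[tuple[str, str], SyntheticConfig],
                 n_subjects: int, seed: int,
                 subject_ids: Mapping[str, Sequence[str]] | None = None,
                 ) -> DatasetBundle:
    """Generate a full dataset: behavioural log + one epoch per trial.

    ``configs`` maps ``(group, condition)`` to a :class:`SyntheticConfig`;
    each group needs both a ``"correct"`` and an ``"incorrect"`` entry.
    Per-trial epochs use the config matching the trial's correctness, so
    incorrect trials carry the latency shifts and the larger fluctuation.
    """
    if not configs:
        raise ValueError("at least one (group, condition) config is required")
    groups = sorted({g for g, _ in configs})
    for g in groups:
        for cond in ("correct", "incorrect"):
            if (g, cond) not in configs:
                raise ValueError(f"missing config for ({g!r}, {cond!r})")

    ss = np.random.SeedSequence(seed)
    group_seeds = ss.spawn(len(groups))
    trials: list[TrialRecord] = []
    epochs: list[ErpEpoch] = []
    for g, gseed in zip(groups, group_seeds):
        log_seed, epoch_seed = gseed.spawn(2)
        ids = None if subject_ids is None else subject_ids[g]
        cfg_correct = configs[(g, "correct")]
        log = make_trial_log(cfg_correct, n_subjects,
                             rng=np.random.default_rng(log_seed),
                             subject_ids=ids)
        erng = np.random.default_rng(epoch_seed)
        for trial in log:
            cfg = configs[(g, "correct" if trial.is_correct else "incorrect")]
            epochs.append(make_erp_epoch(cfg, rng=erng,
                                         subject_id=trial.subject_id,
                                         shape=trial.shape))
        trials.extend(log)

    ids_seen = {t.subject_id for t in trials}
    expected = sum(len({t.subject_id for t in trials if t.group == g})
                   for g in groups)
    if len(ids_seen) != expected:
        raise ValueError("duplicate subject ids across groups")
    return DatasetBundle(epochs=epochs, trials=trials, seed=seed)
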