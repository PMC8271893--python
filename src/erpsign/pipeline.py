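"""End-to-end orchestration: simulate → preprocess → detect → summarise →
classify.

``run_pipeline`` reproduces the study's analysis flow on synthetic data:
per subject x shape x condition averaged traces are preprocessed with a
chosen variant, component latencies are detected, behavioural and
latency tables are built, and both correctness classifiers (GMM
log-likelihood difference, MLP with stratified 4-fold CV) are evaluated
per group.  Everything is reproducible from ``(config, seed)`` and the
report embeds both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import numpy as np

from . import refdata
from .behavior import (LatencySummary, ShapeSummary, aggregate_shape_summaries,
                       latency_gaps, summarize_behavior, summarize_latencies)
from .detect import (ComponentLatencies, DetectionConfig, detect_components,
                     extract_feature_window, resample_features)
from .gmm import GmmModel, fit_gmm_em, loglik_difference
from .io import config_hash
from .mlp import CvResult, MlpConfig, kfold_cv
from .preprocess import PreprocessingVariant, apply_variant, average_epochs
from .synth import DatasetBundle, default_config, make_dataset

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs for one pipeline run.

    ``synthetic_overrides`` are forwarded to :func:`erpsign.synth.default_config`
    for every group/condition (e.g. ``{"noise_sd_uV": 0.0}``).
    """

    groups: tuple[str, ...] = ("elderly", "youth")
    n_subjects: int = 10
    variant: str = "zero_phase_smoothed"
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    mlp: MlpConfig = field(default_factory=MlpConfig)
    gmm_components: int = 10
    feature_points: int = 70
    cv_folds: int = 4
    synthetic_overrides: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in refdata.GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class DetectionRow:
    """One detection-table row: labels plus the detected latencies."""

    subject_id: str
    group: str
    condition: str
    shape: str
    variant: str
    latencies: ComponentLatencies


@dataclass
class PipelineReport:
    """Everything one run computes, with a stable text rendering."""

    seed: int
    cfg_hash: str
    variant: str
    shape_summaries: list[ShapeSummary]
    group_averages: dict[str, ShapeSummary]
    latency_summaries: dict[tuple[str, str], LatencySummary]
    gap_tables: dict[str, dict[str, float]]
    detection_table: list[DetectionRow]
    gmm_models: dict[str, GmmModel]
    gmm_differences: dict[str, tuple[float, float, int]]  # mean, popsd, n subjects
    cv_results: dict[str, CvResult]

    def to_text(self) -> str:
        lines = [
            f"erpsign pipeline report (seed={self.seed}, "
            f"config_hash={self.cfg_hash}, variant={self.variant})",
            "",
            "== Behaviour (per-subject counts) ==",
        ]
        for s in self.shape_summaries:
            lines.append(
                f"{s.group:8s} {s.shape:10s} correct {s.mean_correct:6.2f} "
                f"(sd {s.sd_correct:5.2f})  incorrect {s.mean_incorrect:6.2f} "
                f"(sd {s.sd_incorrect:5.2f})  error rate {100 * s.error_rate:5.1f}%")
        for g, s in sorted(self.group_averages.items()):
            lines.append(
                f"{g:8s} {'avg':10s} correct {s.mean_correct:6.2f} "
                f"(sd {s.sd_correct:5.2f})  incorrect {s.mean_incorrect:6.2f} "
                f"(sd {s.sd_incorrect:5.2f})  error rate {100 * s.error_rate:5.1f}%")
        lines += ["", "== Component latencies (ms) =="]
        for (g, cond), summ in sorted(self.latency_summaries.items()):
            cells = "  ".join(
                f"{c} {summ.mean_ms[c]:6.1f}±{summ.sd_ms[c]:5.1f}"
                for c in refdata.COMPONENTS if c in summ.mean_ms)
            lines.append(f"{g:8s} {cond:10s} {cells}")
        lines += ["", "== Correct-vs-incorrect gap times (ms) =="]
        for g, gaps in sorted(self.gap_tables.items()):
            cells = "  ".join(f"{c} {gaps[c]:+.0f}" for c in refdata.COMPONENTS
                              if c in gaps)
            lines.append(f"{g:8s} {cells}")
        lines += ["", "== GMM log-likelihood difference |LL(corr)|-|LL(inc)| =="]
        for g, (m, s, n) in sorted(self.gmm_differences.items()):
            lines.append(f"{g:8s} mean {m:12.1f}  popsd {s:10.1f}  (n={n} subjects)")
        lines += ["", f"== MLP {len(next(iter(self.cv_results.values())).fold_accuracies) if self.cv_results else 0}-fold cross-validation =="]
        for g, cv in sorted(self.cv_results.items()):
            folds = " ".join(f"{a:.2f}" for a in cv.fold_accuracies)
            lines.append(f"{g:8s} folds [{folds}]  mean {cv.mean:.2f}  "
                         f"popsd {cv.popsd:.2f}")
        return "\n".join(lines) + "\n"


def _averaged_traces(bundle: DatasetBundle, group: str, variant:
                     PreprocessingVariant) -> list[tuple[str, str, str, Any]]:
    """(subject, shape, condition, processed averaged epoch) per cell."""
    out = []
    subjects = sorted({t.subject_id for t in bundle.trials if t.group == group})
    shapes = sorted({t.shape for t in bundle.trials if t.group == group})
    for sid in subjects:
        for shape in shapes:
            for cond in ("correct", "incorrect"):
                eps = bundle.epochs_for(subject_id=sid, shape=shape,
                                        condition=cond)
                if not eps:
                    continue  # e.g. a subject with no incorrect trial here
                avg = average_epochs(eps)
                out.append((sid, shape, cond, apply_variant(avg, variant)))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full synthetic study once; see the module docstring."""
    cfg_hash = config_hash({
        "groups": config.groups, "n_subjects": config.n_subjects,
        "variant": config.variant, "seed": config.seed,
        "detection": config.detection, "mlp": config.mlp,
        "gmm_components": config.gmm_components,
        "feature_points": config.feature_points,
        "cv_folds": config.cv_folds,
        "synthetic_overrides": dict(config.synthetic_overrides),
    })
    variant = PreprocessingVariant(tag=config.variant)
    synth_configs = {
        (g, cond): default_config(g, cond, **dict(config.synthetic_overrides))
        for g in config.groups for cond in ("correct", "incorrect")
    }
    bundle = make_dataset(synth_configs, config.n_subjects, config.seed)

    shape_summaries = summarize_behavior(bundle.trials)
    group_averages = {
        g: aggregate_shape_summaries([s for s in shape_summaries if s.group == g])
        for g in config.groups
    }

    detection_table: list[DetectionRow] = []
    latency_summaries: dict[tuple[str, str], LatencySummary] = {}
    gap_tables: dict[str, dict[str, float]] = {}
    gmm_models: dict[str, GmmModel] = {}
    gmm_differences: dict[str, tuple[float, float, int]] = {}
    cv_results: dict[str, CvResult] = {}

    for g in config.groups:
        traces = _averaged_traces(bundle, g, variant)
        windows: dict[tuple[str, str, str], np.ndarray] = {}
        per_cond_rows: dict[str, list[dict[str, Optional[float]]]] = {
            "correct": [], "incorrect": []}
        for sid, shape, cond, ep in traces:
            lat = detect_components(ep, config.detection,
                                    variant_tag=config.variant)
            detection_table.append(DetectionRow(sid, g, cond, shape,
                                                config.variant, lat))
            per_cond_rows[cond].append(lat.as_dict())
            windows[(sid, shape, cond)] = extract_feature_window(
                ep, lat.n200_ms).amplitude_uV

        for cond in ("correct", "incorrect"):
            latency_summaries[(g, cond)] = summarize_latencies(
                g, cond, per_cond_rows[cond])
        gap_tables[g] = latency_gaps(latency_summaries[(g, "correct")],
                                     latency_summaries[(g, "incorrect")])

        # GMM: correct-answer model on pooled windows, scored per subject
        correct_pool = np.concatenate(
            [w for (sid, sh, cond), w in windows.items() if cond == "correct"])
        model = fit_gmm_em(correct_pool, n_components=config.gmm_components)
        gmm_models[g] = model
        diffs = []
        for sid in sorted({k[0] for k in windows}):
            c = [w for (s, sh, cond), w in windows.items()
                 if s == sid and cond == "correct"]
            i = [w for (s, sh, cond), w in windows.items()
                 if s == sid and cond == "incorrect"]
            if not c or not i:
                warnings.warn(f"subject {sid}: missing a condition, skipped "
                              "in GMM scoring")
                continue
            res = loglik_difference(model, np.concatenate(c), np.concatenate(i))
            diffs.append(res.difference)
        arr = np.asarray(diffs)
        gmm_differences[g] = (float(arr.mean()), float(arr.std(ddof=0)),
                              arr.size)

        # MLP: one feature vector per averaged trace, label 1 = correct
        feats = np.stack([resample_features(w, config.feature_points)
                          for w in windows.values()])
        labels = np.array([1 if k[2] == "correct" else 0 for k in windows])
        cv_results[g] = kfold_cv(feats, labels, k=config.cv_folds,
                                 config=config.mlp, seed=config.seed)

    return PipelineReport(
        seed=config.seed, cfg_hash=cfg_hash, variant=config.variant,
        shape_summaries=shape_summaries, group_averages=group_averages,
        latency_summaries=latency_summaries, gap_tables=gap_tables,
        detection_table=detection_table, gmm_models=gmm_models,
        gmm_differences=gmm_differences, cv_results=cv_results)
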