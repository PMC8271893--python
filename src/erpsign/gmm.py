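"""Correct-answer modelling with a univariate Gaussian mixture.

The correctness classifier of the first (unsupervised) stage: the pooled
amplitude samples of the correct-answer feature windows are clustered
into ``n_components`` Gaussians by expectation-maximisation, and a trace
(or a subject's pooled windows) is scored by its log-likelihood under
that model.  Separation is reported as ``|LL(correct)| - |LL(incorrect)|``;
the more negative the difference, the better the correct/incorrect split,
because data far from the correct-answer model has a much larger
``|LL|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GmmModel",
    "LogLikResult",
    "fit_gmm_em",
    "gmm_loglik",
    "loglik_difference",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GmmModel:
    """Fitted univariate mixture: weights, means, variances per component."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    converged: bool = False
    final_loglik: float = float("nan")
    n_iter: int = 0
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate_components: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        k = self.weights.size
        if self.means.size != k or self.variances.size != k:
            raise ValueError("weights, means and variances must share a length")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_components(self) -> int:
        return self.weights.size


def _log_component_densities(x: np.ndarray, model_means: np.ndarray,
                             model_vars: np.ndarray,
                             model_weights: np.ndarray) -> np.ndarray:
    """(n_samples, k) matrix of log(w_k N(x | mu_k, var_k))."""
    d = x[:, None] - model_means[None, :]
    return (np.log(model_weights)[None, :]
            - 0.5 * (_LOG_2PI + np.log(model_vars))[None, :]
            - 0.5 * d * d / model_vars[None, :])


def fit_gmm_em(samples: Sequence[float], n_components: int = 10,
               seed: int | None = None, tol: float = 1e-6,
               max_iter: int = 500,
               variance_floor_frac: float = 1e-6) -> GmmModel:
    """Fit a univariate Gaussian mixture by expectation-maximisation.

    Initialisation is deterministic: means at the ``(k+0.5)/K`` sample
    quantiles, equal weights, pooled (total) variance — so the fit does
    not depend on ``seed`` (the argument is accepted for interface
    stability and reserved for future random restarts).  Iterations stop
    when the relative log-likelihood improvement drops below ``tol``.
    The log-likelihood is checked to be non-decreasing at every step (an
    EM guarantee; a violation beyond round-off raises).

    Components whose variance collapses below
    ``variance_floor_frac * var(samples)`` are floored and flagged in
    ``degenerate_components``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < n_components:
        raise ValueError(f"need at least {n_components} samples to fit "
                         f"{n_components} components, got {x.size}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    total_var = float(x.var())
    floor = max(variance_floor_frac * total_var, 1e-12)
    means = np.quantile(x, (np.arange(n_components) + 0.5) / n_components)
    variances = np.full(n_components, max(total_var, floor))
    weights = np.full(n_components, 1.0 / n_components)

    history: list[float] = []
    degenerate: set[int] = set()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_wp = _log_component_densities(x, means, variances, weights)
        log_norm = logsumexp(log_wp, axis=1)
        ll = float(log_norm.sum())
        if history and ll < history[-1] - 1e-8 * max(1.0, abs(history[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{history[-1]} -> {ll}")
        if history and ll - history[-1] < tol * abs(history[-1]):
            history.append(ll)
            converged = True
            break
        history.append(ll)

        resp = np.exp(log_wp - log_norm[:, None])  # E-step responsibilities
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        d = x[:, None] - means[None, :]
        variances = (resp * d * d).sum(axis=0) / nk
        low = variances < floor
        if np.any(low):
            degenerate.update(np.flatnonzero(low).tolist())
            variances = np.maximum(variances, floor)

    return GmmModel(weights=weights, means=means, variances=variances,
                    converged=converged, final_loglik=history[-1],
                    n_iter=it, loglik_history=np.asarray(history),
                    degenerate_components=tuple(sorted(degenerate)))


def gmm_loglik(model: GmmModel, samples: Sequence[float]) -> float:
    """Total log-likelihood of ``samples`` under the mixture.

    Computed with log-sum-exp so far-out samples underflow gracefully.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot score an empty sample set")
    log_wp = _log_component_densities(x, model.means, model.variances,
                                      model.weights)
    return float(logsumexp(log_wp, axis=1).sum())


@dataclass(frozen=True)
class LogLikResult:
    """Log-likelihood separation score of one correct/incorrect pair."""

    ll_correct: float
    ll_incorrect: float

    @property
    def difference(self) -> float:
        """``|LL(correct)| - |LL(incorrect)|`` (more negative = better split)."""
        return abs(self.ll_correct) - abs(self.ll_incorrect)


def loglik_difference(model: GmmModel, correct_samples: Sequence[float],
                      incorrect_samples: Sequence[float]) -> LogLikResult:
    """Score a correct/incorrect pair under a correct-answer model."""
    return LogLikResult(ll_correct=gmm_loglik(model, correct_samples),
                        ll_incorrect=gmm_loglik(model, incorrect_samples))
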