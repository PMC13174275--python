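"""Classical ensemble combination baselines.

Four comparison strategies for an M-member ensemble:

* majority voting — each member casts a hard vote I(mu_k >= threshold);
* soft voting — uniform averaging of member probabilities;
* performance weighting — member weights fitted by linear regression of
  validation labels on member probabilities;
* uncertainty voting — per sample, trust the single least-uncertain member.

Soft voting and uncertainty voting are the c = 0 and c -> infinity limits of
the negative-softmax uncertainty weighting scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dune_ensemble.predictions import Labels, MemberPredictions, ValidationError
from dune_ensemble.weighting import EnsembleOutput, WeightMatrix, ensemble_predict
from dune_ensemble.weighting import _normalize  # shared normalisation path

__all__ = [
    "PerformanceWeights",
    "majority_vote",
    "soft_vote",
    "performance_weighting_fit",
    "performance_weighting_predict",
    "uncertainty_vote",
]


@dataclass(frozen=True)
class PerformanceWeights:
    """Linear-regression combination weights fitted on validation data."""

    member_ids: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.shape != (len(self.member_ids),):
            raise ValidationError("one coefficient per member required")
        if not np.all(np.isfinite(coef)) or not np.isfinite(self.intercept):
            raise ValidationError("performance weights must be finite")


def majority_vote(preds: MemberPredictions, threshold: float = 0.5) -> np.ndarray:
    """Hard majority label per sample.

    Each member votes ``I(mu_k >= threshold)``; the output is the majority
    label.  For even M, ties break toward label 1 (mean vote exactly 0.5
    counts as positive).
    """
    votes = (preds.mu >= threshold).astype(float)
    return (votes.mean(axis=0) >= 0.5).astype(np.int64)


def soft_vote(preds: MemberPredictions) -> EnsembleOutput:
    """Uniform-weight ensemble average (w_k = 1/M for every sample)."""
    ones = np.ones_like(preds.mu)
    return ensemble_predict(preds, _normalize(ones, preds))


def performance_weighting_fit(
    val_preds: MemberPredictions, val_labels: Labels
) -> PerformanceWeights:
    """Fit ordinary least squares of validation labels on member probabilities.

    The design matrix is the N x M grid of member mu values plus an
    intercept; coefficients are unconstrained and may be negative.  A
    rank-deficient design (e.g. duplicated members) falls back to the
    minimum-norm pseudoinverse solution with a warning.
    """
    y = val_labels.aligned_to(val_preds.sample_ids).astype(float)
    M, N = val_preds.n_members, val_preds.n_samples
    if N < M + 1:
        raise ValidationError(
            f"need at least M+1={M + 1} validation samples to fit {M} coefficients"
        )
    X = np.column_stack([np.ones(N), val_preds.mu.T])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            "rank-deficient validation design; using minimum-norm pseudoinverse solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return PerformanceWeights(val_preds.member_ids, coef[1:], float(coef[0]))


def performance_weighting_predict(
    preds: MemberPredictions, pw: PerformanceWeights
) -> EnsembleOutput:
    """Apply fitted regression weights: mu_ens = intercept + sum_k coef_k mu_k.

    Predictions are clipped to [0, 1].  The reported ensemble variance is
    ``sum_k coef_k^2 sigma_k^2``, the variance the linear combination
    propagates from the member sigmas.
    """
    if pw.member_ids != preds.member_ids:
        raise ValidationError("performance weights fitted for different member_ids")
    mu_ens = pw.intercept + pw.coefficients @ preds.mu
    var_ens = (pw.coefficients**2) @ (preds.sigma**2)
    return EnsembleOutput(preds.sample_ids, np.clip(mu_ens, 0.0, 1.0), var_ens)


def uncertainty_vote(preds: MemberPredictions) -> EnsembleOutput:
    """Per sample, adopt the prediction of the least-uncertain member.

    ``k* = argmin_k sigma_k`` (ties resolve to the smallest member index);
    the output is (mu_{k*}, sigma_{k*}^2).
    """
    k_star = preds.sigma.argmin(axis=0)
    cols = np.arange(preds.n_samples)
    mu_ens = preds.mu[k_star, cols]
    var_ens = preds.sigma[k_star, cols] ** 2
    return EnsembleOutput(preds.sample_ids, mu_ens, var_ens)
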