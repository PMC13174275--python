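"""Per-sample member weights and the uncertainty-weighted ensemble prediction.

The ensemble prediction for sample x is the weighted average
``mu_ens(x) = sum_k w_k(x) mu_k(x)`` with per-sample weights derived from each
member's predictive standard deviation sigma_k(x):

* ``unbiased`` — inverse-variance weights ``w_k ∝ 1 / sigma_k^2`` (the
  classical minimum-variance combination of independent unbiased estimates);
* ``negative_softmax`` — ``w_k ∝ exp(-c sigma_k)``; c = 0 recovers soft
  voting (uniform weights) and c → ∞ recovers uncertainty voting (all mass on
  the least uncertain member);
* ``kld`` — ``w_k ∝ KL(N(mu_k, sigma_k^2) || N(0.5, sigma_unc^2))``: members
  whose predictive distribution is farthest from a maximally ignorant
  reference classifier get the largest weights.

Weights are explicitly normalised to sum to 1 per sample so the weighted
average stays inside the convex hull of the member means.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from dune_ensemble.predictions import MemberPredictions, ValidationError

__all__ = [
    "WeightingScheme",
    "WeightingConfig",
    "ReferenceDistribution",
    "WeightMatrix",
    "EnsembleOutput",
    "kl_gaussian",
    "weights_unbiased",
    "weights_negative_softmax",
    "weights_kld",
    "ensemble_predict",
    "dune",
]


class WeightingScheme(str, Enum):
    UNBIASED = "unbiased"
    NEGATIVE_SOFTMAX = "negative_softmax"
    KLD = "kld"


@dataclass(frozen=True)
class WeightingConfig:
    """Configuration of the weighting schemes.

    Parameters
    ----------
    scheme:
        One of ``unbiased``, ``negative_softmax``, ``kld``.
    c:
        Negative-softmax control parameter (>= 0).  Larger c concentrates
        mass on low-sigma members; 0 gives uniform weights.  Default 25, the
        middle of the grid {5, 25, 100} used in the experiments.
    sigma_unc:
        Standard deviation of the "uncertain model" reference N(0.5,
        sigma_unc^2) used by the KLD scheme.  Default 0.1, chosen so the
        reference puts essentially all its mass inside [0, 1].
    sigma_floor:
        Small positive floor applied to sigma before any division or KL
        computation; Monte-Carlo aggregation can legitimately produce
        sigma = 0.
    """

    scheme: WeightingScheme | str = WeightingScheme.UNBIASED
    c: float = 25.0
    sigma_unc: float = 0.1
    sigma_floor: float = 1e-8

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", WeightingScheme(self.scheme))
        if self.c < 0:
            raise ValidationError("control parameter c must be >= 0")
        if self.sigma_unc <= 0:
            raise ValidationError("sigma_unc must be > 0")
        if self.sigma_floor <= 0:
            raise ValidationError("sigma_floor must be > 0")


@dataclass(frozen=True)
class ReferenceDistribution:
    """The maximally ignorant binary classifier N(0.5, sd^2)."""

    sd: float = 0.1
    mean: float = 0.5

    def __post_init__(self) -> None:
        if self.mean != 0.5:
            raise ValidationError("reference mean is fixed at 0.5 for binary classification")
        if self.sd <= 0:
            raise ValidationError("reference sd must be > 0")


@dataclass(frozen=True)
class WeightMatrix:
    """Per-sample, per-member normalised weights aligned to a prediction grid."""

    member_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != (len(self.member_ids), len(self.sample_ids)):
            raise ValidationError("weight matrix shape does not match id lists")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValidationError("weights must be finite and >= 0")
        if not np.allclose(w.sum(axis=0), 1.0, rtol=0.0, atol=1e-12):
            raise ValidationError("per-sample weights must sum to 1 within 1e-12")


@dataclass(frozen=True)
class EnsembleOutput:
    """Ensemble mean mu_ens and variance var_ens = sum_k w_k^2 sigma_k^2 per sample."""

    sample_ids: tuple[str, ...]
    mu_ens: np.ndarray
    var_ens: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_ens, dtype=float)
        var = np.asarray(self.var_ens, dtype=float)
        object.__setattr__(self, "mu_ens", mu)
        object.__setattr__(self, "var_ens", var)
        n = len(self.sample_ids)
        if mu.shape != (n,) or var.shape != (n,):
            raise ValidationError("ensemble output vectors must align with sample_ids")
        if np.any(var < 0):
            raise ValidationError("ensemble variance must be >= 0")


def kl_gaussian(p_mean, p_sd, q_mean, q_sd):
    """Closed-form KL divergence KL(N(p_mean, p_sd^2) || N(q_mean, q_sd^2)).

    Returns ``ln(q_sd/p_sd) + (p_sd^2 + (p_mean - q_mean)^2) / (2 q_sd^2) - 1/2``,
    which is >= 0 with equality iff the two distributions coincide.  Accepts
    scalars or broadcastable arrays; standard deviations must be positive.
    """
    p_mean = np.asarray(p_mean, dtype=float)
    p_sd = np.asarray(p_sd, dtype=float)
    q_mean = np.asarray(q_mean, dtype=float)
    q_sd = np.asarray(q_sd, dtype=float)
    if np.any(p_sd <= 0) or np.any(q_sd <= 0):
        raise ValidationError("kl_gaussian requires strictly positive standard deviations")
    out = np.log(q_sd / p_sd) + (p_sd**2 + (p_mean - q_mean) ** 2) / (2.0 * q_sd**2) - 0.5
    # clamp tiny negative round-off at p == q
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def _normalize(raw: np.ndarray, preds: MemberPredictions) -> WeightMatrix:
    totals = raw.sum(axis=0)
    w = raw / totals
    # renormalise exactly to absorb summation round-off
    w = w / w.sum(axis=0)
    return WeightMatrix(preds.member_ids, preds.sample_ids, w)


def weights_unbiased(preds: MemberPredictions, cfg: WeightingConfig) -> WeightMatrix:
    """Inverse-variance weights ``w_k ∝ 1 / max(sigma_k, floor)^2``."""
    sigma = np.maximum(preds.sigma, cfg.sigma_floor)
    return _normalize(1.0 / sigma**2, preds)


def weights_negative_softmax(preds: MemberPredictions, cfg: WeightingConfig) -> WeightMatrix:
    """Negative-softmax weights ``w_k ∝ exp(-c sigma_k)``.

    Stabilised by subtracting the per-sample minimum of ``c sigma_k`` before
    exponentiation, which leaves the normalised weights unchanged but keeps
    very large c (e.g. 1e6) free of underflow-to-all-zeros.
    """
    scores = -cfg.c * preds.sigma
    scores = scores - scores.max(axis=0)  # == subtracting min of c*sigma
    return _normalize(np.exp(scores), preds)


def weights_kld(preds: MemberPredictions, cfg: WeightingConfig) -> WeightMatrix:
    """KL-divergence weights ``w_k ∝ KL(N(mu_k, sigma_k^2) || N(0.5, sigma_unc^2))``.

    If every member of a sample exactly equals the reference (all divergences
    zero) the weights fall back to uniform for that sample.
    """
    sigma = np.maximum(preds.sigma, cfg.sigma_floor)
    raw = kl_gaussian(preds.mu, sigma, 0.5, cfg.sigma_unc)
    raw = np.asarray(raw, dtype=float)
    degenerate = raw.sum(axis=0) == 0.0
    if np.any(degenerate):
        raw[:, degenerate] = 1.0
    return _normalize(raw, preds)


_SCHEME_FUNCS = {
    WeightingScheme.UNBIASED: weights_unbiased,
    WeightingScheme.NEGATIVE_SOFTMAX: weights_negative_softmax,
    WeightingScheme.KLD: weights_kld,
}


def ensemble_predict(preds: MemberPredictions, weights: WeightMatrix) -> EnsembleOutput:
    """Weighted ensemble mean and variance.

    ``mu_ens(x) = sum_k w_k(x) mu_k(x)`` and
    ``var_ens(x) = sum_k w_k(x)^2 sigma_k(x)^2``.
    """
    if (
        weights.member_ids != preds.member_ids
        or weights.sample_ids != preds.sample_ids
    ):
        raise ValidationError("weight matrix is not aligned with the prediction grid")
    mu_ens = np.einsum("mn,mn->n", weights.w, preds.mu)
    var_ens = np.einsum("mn,mn->n", weights.w**2, preds.sigma**2)
    # weighted averages of values in [0,1] can exceed bounds only by round-off
    return EnsembleOutput(preds.sample_ids, np.clip(mu_ens, 0.0, 1.0), var_ens)


def compute_weights(preds: MemberPredictions, cfg: WeightingConfig) -> WeightMatrix:
    """Dispatch to the configured weighting scheme."""
    try:
        fn = _SCHEME_FUNCS[WeightingScheme(cfg.scheme)]
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"unknown weighting scheme {cfg.scheme!r}") from exc
    return fn(preds, cfg)


def dune(preds: MemberPredictions, cfg: WeightingConfig) -> EnsembleOutput:
    """Uncertainty-weighted ensemble prediction under the configured scheme."""
    return ensemble_predict(preds, compute_weights(preds, cfg))
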