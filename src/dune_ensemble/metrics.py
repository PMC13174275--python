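"""Uncertainty and classification metrics.

Implements the Cross-Divergence (CDiv) uncertainty metric alongside the
standard calibration metrics — expected calibration error (ECE), Brier score
and negative log-likelihood (NLL) — plus threshold classification metrics,
Table-style stratified-sigma summaries (sigma by TP/TN/FP/FN category), and
candidate ranking by ensemble probability.

CDiv for member k on sample x with label y is

    cd_k(x) = (y ln(2 mu_k) + (1 - y) ln(2 - 2 mu_k))
              * KL( N(mu_k, sigma_k^2) || N(0.5, sigma_unc^2) )

The first factor is positive when mu_k is on the correct side of 0.5 and
strongly negative when it is confidently wrong; the KL factor measures how
far the member's predictive distribution sits from a maximally ignorant
reference classifier.  Unlike ECE/NLL/Brier, CDiv therefore reacts to the
predictive standard deviation, not only to the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from dune_ensemble.predictions import Labels, MemberPredictions, ValidationError
from dune_ensemble.weighting import EnsembleOutput, kl_gaussian

__all__ = [
    "MetricConfig",
    "CDivReport",
    "MetricReport",
    "cdiv_member",
    "cdiv_ensemble",
    "ece",
    "brier",
    "nll",
    "classification_metrics",
    "stratified_sigma",
    "rank_candidates",
]

CATEGORIES = ("TP", "TN", "FP", "FN")


@dataclass(frozen=True)
class MetricConfig:
    """Shared metric settings.

    theta_d : decision threshold for hard labels, default 0.5.
    n_bins : number of equal-width confidence bins for ECE, default 10.
    prob_eps : clamp applied to probabilities inside logarithms, default 1e-12.
    sigma_unc : reference sd for the CDiv KL term, default 0.1.
    sigma_floor : floor applied to sigma before the KL term, default 1e-8.
    """

    theta_d: float = 0.5
    n_bins: int = 10
    prob_eps: float = 1e-12
    sigma_unc: float = 0.1
    sigma_floor: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_d < 1.0:
            raise ValidationError("theta_d must lie in (0, 1)")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if self.prob_eps <= 0 or self.sigma_unc <= 0 or self.sigma_floor <= 0:
            raise ValidationError("prob_eps, sigma_unc and sigma_floor must be > 0")


@dataclass(frozen=True)
class CDivReport:
    """Cross-Divergence summary: per member, per sample, and overall mean."""

    member_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    per_member: np.ndarray  # dataset mean of cd_k, length M
    per_sample: np.ndarray  # member-averaged cd(x), length N
    overall: float  # dataset mean of cd(x)


@dataclass(frozen=True)
class MetricReport:
    """Flat bundle of classification and uncertainty metrics for one prediction set."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float  # NaN when labels are single-class
    ece: float | None = None
    nll: float | None = None
    brier: float | None = None
    cdiv_overall: float | None = None

    def to_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
        }
        for key in ("ece", "nll", "brier", "cdiv_overall"):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        return d


def _as_prob_vector(y_hat) -> np.ndarray:
    y_hat = np.asarray(y_hat, dtype=float)
    if np.any(y_hat < 0) or np.any(y_hat > 1) or not np.all(np.isfinite(y_hat)):
        raise ValidationError("predicted probabilities must lie in [0, 1]")
    return y_hat


def cdiv_member(mu, sigma, y, cfg: MetricConfig = MetricConfig()) -> np.ndarray | float:
    """Cross-Divergence of a single member's predictions against labels.

    Vectorised over samples.  mu is clamped to [prob_eps, 1 - prob_eps]
    inside the logarithms only; sigma is floored before the KL term.
    Returns 0 exactly at mu = 0.5, positive when the prediction is on the
    correct side of 0.5, strongly negative when confidently wrong.
    """
    mu = _as_prob_vector(mu)
    sigma = np.asarray(sigma, dtype=float)
    y = np.asarray(y)
    mu_c = np.clip(mu, cfg.prob_eps, 1.0 - cfg.prob_eps)
    correctness = y * np.log(2.0 * mu_c) + (1 - y) * np.log(2.0 - 2.0 * mu_c)
    kl = kl_gaussian(mu, np.maximum(sigma, cfg.sigma_floor), 0.5, cfg.sigma_unc)
    out = correctness * kl
    return float(out) if np.ndim(out) == 0 else out


def cdiv_ensemble(
    preds: MemberPredictions, labels: Labels, cfg: MetricConfig = MetricConfig()
) -> CDivReport:
    """Cross-Divergence of an ensemble: cd(x) = mean over members of cd_k(x).

    The dataset-level number is the mean of cd(x) over samples; per-member
    dataset means are reported alongside.
    """
    y = labels.aligned_to(preds.sample_ids)
    cd = np.vstack(
        [cdiv_member(preds.mu[k], preds.sigma[k], y, cfg) for k in range(preds.n_members)]
    )
    per_sample = cd.mean(axis=0)
    return CDivReport(
        member_ids=preds.member_ids,
        sample_ids=preds.sample_ids,
        per_member=cd.mean(axis=1),
        per_sample=per_sample,
        overall=float(per_sample.mean()),
    )


def ece(y_hat, labels: Labels | np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    """Expected calibration error over equal-width confidence bins.

    Each sample's confidence is the probability assigned to its predicted
    label ``y_tilde = I(y_hat >= theta_d)`` — i.e. ``y_hat`` when predicting
    the positive class and ``1 - y_hat`` otherwise.  [0, 1] is split into
    ``n_bins`` half-open bins [lo, hi), the last bin closed at 1; within bin
    B, conf(B) is the mean confidence and acc(B) the fraction of samples
    whose predicted label matches the truth.  ECE is the bin-size-weighted
    mean |acc - conf|; empty bins contribute 0.  A perfect hard predictor
    scores 0 and a calibrated probabilistic predictor approaches 0 with N.
    """
    y_hat = _as_prob_vector(y_hat)
    y = labels.y if isinstance(labels, Labels) else np.asarray(labels)
    pred = (y_hat >= cfg.theta_d).astype(int)
    conf_i = np.where(pred == 1, y_hat, 1.0 - y_hat)
    correct = (pred == y).astype(float)
    bins = np.minimum((conf_i * cfg.n_bins).astype(int), cfg.n_bins - 1)
    total = 0.0
    n = len(y_hat)
    for b in range(cfg.n_bins):
        mask = bins == b
        size = int(mask.sum())
        if size == 0:
            continue
        total += (size / n) * abs(correct[mask].mean() - conf_i[mask].mean())
    return float(total)


def brier(y_hat, labels: Labels | np.ndarray) -> float:
    """Mean squared error between predicted probability and binary label."""
    y_hat = _as_prob_vector(y_hat)
    y = labels.y if isinstance(labels, Labels) else np.asarray(labels)
    return float(np.mean((y - y_hat) ** 2))


def nll(y_hat, labels: Labels | np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    """Mean negative log-probability of the true label, with clamped probabilities."""
    y_hat = _as_prob_vector(y_hat)
    y = labels.y if isinstance(labels, Labels) else np.asarray(labels)
    p = np.clip(y_hat, cfg.prob_eps, 1.0 - cfg.prob_eps)
    return float(np.mean(-y * np.log(p) - (1 - y) * np.log(1.0 - p)))


def classification_metrics(
    y_hat, labels: Labels | np.ndarray, cfg: MetricConfig = MetricConfig()
) -> MetricReport:
    """Accuracy, precision, recall, F1 and AUC-ROC at threshold theta_d.

    Precision/recall/F1 use the 0/0 -> 0 convention; AUC-ROC is the
    tie-aware (midrank) Mann-Whitney statistic and is reported as NaN with a
    warning when the labels contain a single class.
    """
    y_hat = _as_prob_vector(y_hat)
    y = labels.y if isinstance(labels, Labels) else np.asarray(labels)
    y_pred = (y_hat >= cfg.theta_d).astype(int)
    if len(np.unique(y)) < 2:
        warnings.warn("AUC-ROC undefined for single-class labels", RuntimeWarning, stacklevel=2)
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, y_hat))
    return MetricReport(
        accuracy=float(accuracy_score(y, y_pred)),
        precision=float(precision_score(y, y_pred, zero_division=0)),
        recall=float(recall_score(y, y_pred, zero_division=0)),
        f1=float(f1_score(y, y_pred, zero_division=0)),
        auc_roc=auc,
    )


def evaluate_probabilities(
    y_hat,
    labels: Labels | np.ndarray,
    cfg: MetricConfig = MetricConfig(),
    member_preds: MemberPredictions | None = None,
) -> MetricReport:
    """Full metric bundle for one probability vector (CDiv needs member grids)."""
    base = classification_metrics(y_hat, labels, cfg)
    cdiv = None
    if member_preds is not None:
        lab = labels if isinstance(labels, Labels) else Labels(member_preds.sample_ids, labels)
        cdiv = cdiv_ensemble(member_preds, lab, cfg).overall
    return MetricReport(
        accuracy=base.accuracy,
        precision=base.precision,
        recall=base.recall,
        f1=base.f1,
        auc_roc=base.auc_roc,
        ece=ece(y_hat, labels, cfg),
        nll=nll(y_hat, labels, cfg),
        brier=brier(y_hat, labels),
        cdiv_overall=cdiv,
    )


def stratified_sigma(
    preds: MemberPredictions, labels: Labels, cfg: MetricConfig = MetricConfig()
) -> pd.DataFrame:
    """Per-member sigma summaries stratified by TP/TN/FP/FN category.

    Each sample is categorised per member by comparing the hard label
    I(mu_k >= theta_d) against the truth.  Returns a long-format frame with
    columns ``member_id, category, mean_sigma, std_sigma, count`` (population
    std; empty categories carry count 0 and NaN means).  Per member the four
    counts sum to N.
    """
    y = labels.aligned_to(preds.sample_ids)
    rows = []
    for k, member in enumerate(preds.member_ids):
        pred_pos = preds.mu[k] >= cfg.theta_d
        masks = {
            "TP": pred_pos & (y == 1),
            "TN": ~pred_pos & (y == 0),
            "FP": pred_pos & (y == 0),
            "FN": ~pred_pos & (y == 1),
        }
        for cat in CATEGORIES:
            sig = preds.sigma[k][masks[cat]]
            rows.append(
                {
                    "member_id": member,
                    "category": cat,
                    "mean_sigma": float(sig.mean()) if sig.size else float("nan"),
                    "std_sigma": float(sig.std()) if sig.size else float("nan"),
                    "count": int(sig.size),
                }
            )
    return pd.DataFrame(rows)


def rank_candidates(ens: EnsembleOutput) -> pd.DataFrame:
    """Rank samples by ensemble positive-class probability, descending.

    Ranks are 1-based competition ranks: tied probabilities share the
    smaller rank and are listed in sample_id order for determinism.  Returns
    a frame with columns ``rank, sample_id, p_hat``.
    """
    mu = ens.mu_ens
    order = sorted(range(len(mu)), key=lambda i: (-mu[i], ens.sample_ids[i]))
    ranks = {}
    for pos, i in enumerate(order):
        # competition ("min") rank: 1 + number of strictly greater scores
        ranks[i] = 1 + int(np.sum(mu > mu[i]))
    return pd.DataFrame(
        {
            "rank": [ranks[i] for i in order],
            "sample_id": [ens.sample_ids[i] for i in order],
            "p_hat": [mu[i] for i in order],
        }
    )
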