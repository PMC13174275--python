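"""Seeded synthetic generator of probabilistic classifier ensembles.

The generator emulates the statistical structure that uncertainty-weighted
aggregation exploits: an M-member ensemble of probabilistic binary
classifiers whose predictive standard deviation sigma is systematically
lower for correct than for incorrect predictions.

Generative model per sample x:

1. draw the label y ~ Bernoulli(pos_rate);
2. per member k, draw a latent score z = skill_k * (2y - 1) + eps with
   eps ~ N(0, 1) — skill_k is the member's signal-to-noise ratio, so its
   marginal accuracy is Phi(skill_k);
3. set mu_k = logistic(z), or in calibrated mode the exact posterior
   P(y = 1 | z) = logistic(2 skill_k z + logit(pos_rate)), which makes mu a
   perfectly calibrated probability;
4. classify the prediction as correct iff I(mu_k >= 0.5) == y, then draw
   sigma_k from a lognormal whose (location, scale) depend on correctness.

sigma is drawn conditionally on correctness rather than derived from a
mechanistic model: that directly instantiates the empirical pattern (low
sigma on true positives/negatives, high sigma on errors) without asserting a
mechanism, and makes the gap an explicit dial — setting the correct and
incorrect lognormals equal removes all uncertainty signal.

Member-level randomness uses substreams derived from (seed, member index),
so adding a member never perturbs the draws of earlier members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from dune_ensemble.predictions import (
    Labels,
    McDraws,
    MemberPredictions,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "simulate_ensemble",
    "simulate_mc_draws",
    "beta_draws_from_predictions",
]

#: default lognormal locations for sigma: correct predictions centre near
#: 0.005, incorrect near 0.02 — the magnitudes typical of dropout-based
#: predictive spreads on held-out protein data.  The shared scale 0.25 keeps
#: the within-category spread moderate, so when the correct/incorrect gap is
#: disabled the inverse-variance weights stay close to uniform and carry no
#: correctness signal.
DEFAULT_SIGMA_CORRECT = (math.log(0.005), 0.25)
DEFAULT_SIGMA_INCORRECT = (math.log(0.02), 0.25)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic ensemble generator.

    n_samples, n_members : grid size (default 5 members, the usual ensemble
        size for this kind of protein-property model).
    pos_rate : prior positive fraction in (0, 1).
    member_skill : per-member latent signal-to-noise; member accuracy is
        Phi(skill).  None spreads skills evenly over [1.0, 1.4]
        (accuracies ~0.84-0.92, the realistic range for these classifiers).
    sigma_correct, sigma_incorrect : (location, scale) of the lognormal that
        sigma is drawn from for correct / incorrect predictions.
    calibrated : if True, mu is the exact posterior P(y=1 | z) so the
        generator is perfectly calibrated by construction.
    seed : master seed; every stream derives from it deterministically.
    """

    n_samples: int
    n_members: int = 5
    pos_rate: float = 0.5
    member_skill: tuple[float, ...] | None = None
    sigma_correct: tuple[float, float] = DEFAULT_SIGMA_CORRECT
    sigma_incorrect: tuple[float, float] = DEFAULT_SIGMA_INCORRECT
    calibrated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_members < 1:
            raise ValidationError("n_samples and n_members must be >= 1")
        if not 0.0 < self.pos_rate < 1.0:
            raise ValidationError("pos_rate must lie in (0, 1)")
        for loc, scale in (self.sigma_correct, self.sigma_incorrect):
            if scale <= 0:
                raise ValidationError("lognormal scale parameters must be > 0")
        if self.member_skill is not None:
            skills = tuple(float(s) for s in self.member_skill)
            if len(skills) != self.n_members or any(s < 0 for s in skills):
                raise ValidationError("member_skill needs one value >= 0 per member")
            object.__setattr__(self, "member_skill", skills)

    @property
    def skills(self) -> np.ndarray:
        if self.member_skill is not None:
            return np.asarray(self.member_skill, dtype=float)
        if self.n_members == 1:
            return np.array([1.2])
        return np.linspace(1.0, 1.4, self.n_members)


def _label_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 0])


def _member_rng(cfg: SimulationConfig, k: int, stream: int = 1) -> np.random.Generator:
    # stream 1: (mu, sigma) generation; stream 2: Monte-Carlo draws
    return np.random.default_rng([cfg.seed, stream, k + 1])


def simulate_ensemble(cfg: SimulationConfig) -> tuple[MemberPredictions, Labels]:
    """Generate an (M, N) prediction grid and matching labels from ``cfg``."""
    rng = _label_rng(cfg)
    y = (rng.random(cfg.n_samples) < cfg.pos_rate).astype(np.int64)
    direction = 2.0 * y - 1.0

    skills = cfg.skills
    mu = np.empty((cfg.n_members, cfg.n_samples))
    sigma = np.empty_like(mu)
    logit_prior = math.log(cfg.pos_rate / (1.0 - cfg.pos_rate))
    for k in range(cfg.n_members):
        mrng = _member_rng(cfg, k)
        z = skills[k] * direction + mrng.standard_normal(cfg.n_samples)
        if cfg.calibrated:
            # exact posterior for the two-Gaussian latent mixture
            mu[k] = expit(2.0 * skills[k] * z + logit_prior)
        else:
            mu[k] = expit(z)
        correct = (mu[k] >= 0.5).astype(int) == y
        loc_c, scale_c = cfg.sigma_correct
        loc_i, scale_i = cfg.sigma_incorrect
        sig_c = mrng.lognormal(mean=loc_c, sigma=scale_c, size=cfg.n_samples)
        sig_i = mrng.lognormal(mean=loc_i, sigma=scale_i, size=cfg.n_samples)
        sigma[k] = np.where(correct, sig_c, sig_i)

    member_ids = tuple(f"m{k + 1}" for k in range(cfg.n_members))
    sample_ids = tuple(f"s{j + 1}" for j in range(cfg.n_samples))
    preds = MemberPredictions(member_ids, sample_ids, mu, sigma)
    return preds, Labels(sample_ids, y)


def beta_draws_from_predictions(
    preds: MemberPredictions, n_draws: int, seed: int
) -> McDraws:
    """Emit moment-matched Beta draws around each (mu, sigma) cell.

    Each cell's draws come from a Beta distribution with mean mu and
    standard deviation min(sigma, 0.95 sqrt(mu (1 - mu))) — the cap keeps
    the variance strictly inside the Beta feasibility bound.  Cells with
    sigma = 0 or mu in {0, 1} degenerate to constant draws.
    """
    if n_draws < 2:
        raise ValidationError("cannot estimate spread: need n_draws >= 2")
    M, N = preds.n_members, preds.n_samples
    draws = np.empty((M, N, n_draws))
    for k in range(M):
        rng = np.random.default_rng([seed, 2, k + 1])
        m = preds.mu[k]
        bound = np.sqrt(m * (1.0 - m))
        s = np.minimum(preds.sigma[k], 0.95 * bound)
        v = s**2
        degenerate = (v <= 0.0) | (bound <= 0.0)
        nu = np.where(degenerate, 1.0, m * (1.0 - m) / np.where(v > 0, v, 1.0) - 1.0)
        if np.any(nu[~degenerate] <= 0):
            raise AssertionError("Beta feasibility violated despite capping")
        alpha = np.where(degenerate, 1.0, m * nu)
        beta = np.where(degenerate, 1.0, (1.0 - m) * nu)
        cell = rng.beta(alpha[:, None], beta[:, None], size=(N, n_draws))
        cell = np.where(degenerate[:, None], m[:, None], cell)
        draws[k] = np.clip(cell, 0.0, 1.0)
    return McDraws(preds.member_ids, preds.sample_ids, draws)


def simulate_mc_draws(cfg: SimulationConfig, n_draws: int) -> McDraws:
    """Simulate an ensemble and emit ``n_draws`` Monte-Carlo draws per cell.

    The underlying (mu, sigma) grid is exactly ``simulate_ensemble(cfg)``,
    so aggregating the returned draws recovers it up to sampling error.
    """
    preds, _ = simulate_ensemble(cfg)
    return beta_draws_from_predictions(preds, n_draws, cfg.seed)
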