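# Methods

## Model and assumptions

Each of M ensemble members is a probabilistic binary classifier whose
prediction for sample x is summarised as a Gaussian N(μ_k(x), σ_k(x)²):
μ_k is the positive-class probability and σ_k the predictive standard
deviation, typically the spread of Monte-Carlo forward passes.  The
Gaussian summary is an approximation — probabilities live on [0, 1] and a
Beta summary would respect the support — but it makes the weighting
closed-form and the KL divergence analytic.  The ensemble prediction is the
weighted average μ_ens = Σ w_k μ_k with per-sample weights normalised to
the simplex, so μ_ens always lies in the convex hull of the member means;
the propagated variance Σ w_k² σ_k² assumes member errors are independent.

### Weighting schemes

* **Inverse-variance (`unbiased`)** — w_k ∝ 1/σ_k².  With weights on the
  simplex this is the minimum-variance combination of independent unbiased
  estimates: for each sample it minimises Σ w_k² σ_k² (verified against a
  dense simplex grid in the tests).
* **Negative-softmax (`negative_softmax`)** — w_k ∝ exp(−c σ_k).  The
  control parameter c (unitless, ≥ 0) interpolates between uniform
  averaging (c = 0) and winner-takes-all selection of the least-uncertain
  member (c → ∞).  The implementation subtracts the per-sample minimum of
  c·σ_k before exponentiation, which leaves normalised weights unchanged
  but supports c as large as 10⁶ without underflowing every term; the
  library treats c = 10⁶ as an exact stand-in for the uncertainty-voting
  limit whenever per-sample σ minima are separated by ≳ 10/c.
* **KL-divergence (`kld`)** — w_k ∝ KL(N(μ_k, σ_k²) ‖ N(0.5, σ_unc²)).
  The reference N(0.5, 0.1²) models a maximally ignorant binary
  classifier: centred on indifference, broad enough that essentially all
  its mass covers [0, 1].  Members far from ignorance (sharp and/or
  decisive) get large weights.  Note KL is not monotone in σ_k: it rises
  again for σ_k > σ_unc; no correction is applied.  If every member of a
  sample coincides exactly with the reference, all divergences are zero
  and the weights fall back to uniform rather than dividing 0/0.

### Baselines

Majority voting (hard votes at the decision threshold, even-M ties broken
toward the positive class), soft voting (uniform weights, implemented on
the identical code path as the c = 0 negative-softmax so the equivalence is
bitwise), uncertainty voting (per-sample argmin σ, ties to the smallest
member index), and performance weighting (unregularised OLS of validation
labels on member probabilities with an intercept; coefficients may be
negative, predictions are clipped to [0, 1], rank-deficient designs fall
back to the minimum-norm pseudoinverse with a warning).

### Cross-Divergence

cd_k(x) = (y ln 2μ_k + (1−y) ln(2−2μ_k)) · KL(N(μ_k, σ_k²) ‖ N(0.5, σ_unc²)).
The correctness factor is 0 at μ = 0.5, positive on the correct side,
and diverges to −∞ as the prediction approaches the wrong label with
certainty; μ is clamped to [1e−12, 1−1e−12] inside the logarithms so
μ ∈ {0, 1} yields a large finite value instead of ±∞.  The ensemble value
cd(x) is the member mean, and the dataset-level number reported everywhere
is the mean of cd(x) over samples (the reduction is a package choice; a sum
would scale with N).  For a fixed correct μ ≠ 0.5, cd_k decreases strictly
in σ on (0, σ_unc), matching the intuition that a sharper correct
prediction is more confident.

## Metrics

* **ECE** — equal-width bins (default 10) over per-sample confidence, where
  confidence is the probability assigned to the *predicted* label
  I(ŷ ≥ θ_d): ŷ when predicting positive, 1−ŷ otherwise; bin score is
  |mean accuracy − mean confidence|, weighted by bin occupancy, empty bins
  contribute 0, last bin closed.  Binning by the predicted-label confidence
  (the standard choice in the deep-learning calibration literature) makes a
  perfect hard predictor score exactly 0 and a calibrated probabilistic
  predictor approach 0 with N; binning by the raw positive-class
  probability with label-match accuracy would penalise confident correct
  negatives.  Known blind spot, kept deliberately: a constant ŷ = 0.5
  predictor on balanced labels scores 0.
* **Brier** — mean (y − ŷ)²; **NLL** — mean −ln p(y), probabilities
  clamped by 1e−12 (so a confidently wrong ŷ = 0 on y = 1 contributes
  ≈ 27.6, not ∞).
* Classification metrics at threshold θ_d = 0.5, precision/recall/F1 with
  the 0/0 → 0 convention, AUC-ROC tie-aware (midrank); AUC is reported as
  NaN with a warning when labels are single-class.
* **Stratified σ** — per member, samples are split into TP/TN/FP/FN by
  I(μ_k ≥ θ_d) vs y; mean and population standard deviation of σ_k per
  category.  Population (denominator n) standard deviations are used here
  and in Monte-Carlo aggregation throughout.

## Synthetic-data generator

Per sample: y ~ Bernoulli(pos_rate); per member, a latent score
z = skill_k(2y−1) + ε, ε ~ N(0,1), and μ_k = logistic(z) — or, in
calibrated mode, the exact posterior P(y=1|z) = logistic(2·skill_k·z +
logit(pos_rate)), which makes μ a perfectly calibrated probability by
construction.  σ_k is then drawn from a lognormal whose parameters depend
on whether the member is correct (I(μ_k ≥ 0.5) = y).

Defaults and why:

* `n_members = 5`, `pos_rate = 0.5`.
* `member_skill`: evenly spread over [1.0, 1.4] unless given; member
  accuracy is Φ(skill) ≈ 0.84–0.92, the realistic range for this class of
  protein-property classifiers.
* `sigma_correct = (ln 0.005, 0.25)`, `sigma_incorrect = (ln 0.02, 0.25)`
  (lognormal location, scale).  The locations reproduce the magnitudes and
  the ~4× correct/incorrect gap seen in dropout-based predictive spreads;
  lognormal gives positive support and right skew.  The shared scale 0.25
  keeps within-category spread moderate: it is chosen so that when the gap
  is disabled (`sigma_incorrect = sigma_correct`) the inverse-variance
  weights are only mildly non-uniform and uncertainty weighting neither
  helps nor hurts (|Δaccuracy| < 0.01 vs soft voting on average) — σ then
  carries no correctness signal, and the generator should not smuggle one
  in through weight concentration alone.
* Member-level substreams are seeded from (seed, stream, member index), so
  adding a member never perturbs earlier members' draws, and labels have
  their own stream.

σ is drawn *conditionally on correctness* rather than derived from a
mechanistic model of the classifier: the package encodes the empirical
observation (correct predictions come with smaller predictive spread), not
a mechanism for it.  Consequently the simulator says nothing about *why*
real ensembles show the gap, and passing tests demonstrate that the
weighting exploits such a gap when present — not that any particular real
ensemble has one.  Other idealisations: members are conditionally
independent given y (real members share training data and architecture
biases and are positively correlated, so real-world gains from averaging
are smaller), σ is independent of μ's distance from 0.5 within a
correctness class, and class-conditional noise is Gaussian.

Monte-Carlo draw emulation (`simulate_mc_draws`) emits, per (member,
sample) cell, Beta-distributed probability draws moment-matched to
(μ, σ), with σ capped at 0.95·√(μ(1−μ)) to stay strictly inside the Beta
feasibility bound; σ = 0 or μ ∈ {0, 1} cells degenerate to constant draws.
Aggregation recovers μ to ±0.02 and σ to ±35 % relative at σ = 0.05 with
the default 64 draws per cell.

## Numerical choices

* σ floor 1e−8 before any division or KL term — Monte-Carlo aggregation
  legitimately produces σ = 0 (all draws identical).
* Weight matrices renormalised a second time after division to absorb
  summation round-off; the per-sample sum-to-1 invariant is enforced at
  1e−12.
* Tables are serialised with 17 significant digits and parsed with
  round-trip float precision, so write∘read is the identity bit-for-bit.
* Ranking uses 1-based competition ranks (ties share the smaller rank) with
  ties listed in sample_id order for determinism.
* OLS via `numpy.linalg.lstsq` (minimum-norm solution doubles as the
  rank-deficient fallback); metric primitives
  (accuracy/precision/recall/F1/AUC) via scikit-learn.

## Problem sizes

The default synthetic study — and what `scripts/acceptance.py` runs — uses
M = 5 members, N = 2000 test samples, 500 validation samples for the
performance-weighting fit, 20 seeds for the accuracy-ordering comparison,
and 64 Monte-Carlo draws per cell; these sizes give Monte-Carlo error well
below the effects being measured while keeping a full run in the order of
seconds.

## Known limitations

* The Gaussian predictive summary ignores the bounded support of
  probabilities; for σ comparable to min(μ, 1−μ) the KL-based quantities
  treat mass outside [0, 1] as real.
* CDiv is unbounded below; a single confidently wrong member can dominate a
  dataset mean.  No tempering or clipping is applied to KLD weights either,
  by design.
* All methods are strictly binary; no multi-class generalisation of CDiv or
  of the confidence binning is provided.
* Performance weighting is plain OLS — no nonnegativity or sum-to-one
  constraint, no regularisation — so with few validation samples the fitted
  combination can extrapolate poorly (predictions are clipped to [0, 1]).
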