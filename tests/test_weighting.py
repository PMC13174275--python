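"""Weighting schemes, KL divergence, and the weighted ensemble prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from dune_ensemble import (
    MemberPredictions,
    WeightingConfig,
    dune,
    ensemble_predict,
    kl_gaussian,
    soft_vote,
    uncertainty_vote,
    weights_kld,
    weights_negative_softmax,
    weights_unbiased,
)
from dune_ensemble.predictions import ValidationError
from dune_ensemble.weighting import WeightMatrix

from conftest import make_random_preds


def kl_quadrature(p_mean, p_sd, q_mean, q_sd):
    """Independent oracle: numerically integrate p(x) ln(p(x)/q(x))."""

    def integrand(x):
        lp = norm.logpdf(x, p_mean, p_sd)
        lq = norm.logpdf(x, q_mean, q_sd)
        return np.exp(lp) * (lp - lq)

    lo, hi = p_mean - 12 * p_sd, p_mean + 12 * p_sd
    val, _ = quad(integrand, lo, hi, limit=200)
    return val


def one_sample_preds(sigmas, mus=None):
    sig = np.asarray(sigmas, dtype=float).reshape(-1, 1)
    if mus is None:
        mus = np.linspace(0.1, 0.9, len(sig))
    mu = np.asarray(mus, dtype=float).reshape(-1, 1)
    ids = tuple(f"m{k}" for k in range(len(sig)))
    return MemberPredictions(ids, ("s0",), mu, sig)


class TestKlGaussian:
    def test_self_divergence_is_zero(self):
        assert kl_gaussian(0.3, 0.05, 0.3, 0.05) == 0.0

    @pytest.mark.parametrize(
        "p_mean, p_sd, expected",
        [(0.8, 0.01, 6.307585), (0.8, 0.05, 4.818147)],
    )
    def test_reference_divergences_match_quadrature(self, p_mean, p_sd, expected):
        closed = kl_gaussian(p_mean, p_sd, 0.5, 0.1)
        assert closed == pytest.approx(expected, abs=1e-6)
        assert closed == pytest.approx(kl_quadrature(p_mean, p_sd, 0.5, 0.1), abs=1e-6)

    def test_confidence_ordering(self):
        # the sharper distribution is farther from the ignorant reference
        assert kl_gaussian(0.8, 0.01, 0.5, 0.1) > kl_gaussian(0.8, 0.05, 0.5, 0.1)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationError):
            kl_gaussian(0.5, 0.0, 0.5, 0.1)
        with pytest.raises(ValidationError):
            kl_gaussian(0.5, 0.1, 0.5, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_parameters_nonnegative_and_match_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        p_mean, q_mean = rng.uniform(0, 1, 2)
        p_sd, q_sd = rng.uniform(0.01, 0.5, 2)
        closed = kl_gaussian(p_mean, p_sd, q_mean, q_sd)
        assert closed >= 0.0
        assert closed == pytest.approx(kl_quadrature(p_mean, p_sd, q_mean, q_sd), abs=1e-6)


class TestUnbiasedWeights:
    def test_equal_sigma_gives_equal_weights(self):
        w = weights_unbiased(one_sample_preds([0.1, 0.1]), WeightingConfig())
        np.testing.assert_allclose(w.w[:, 0], [0.5, 0.5])

    def test_hand_normalised_precisions(self):
        # precisions 1/0.01^2 = 10000 and 1/0.02^2 = 2500 -> weights 0.8, 0.2
        w = weights_unbiased(one_sample_preds([0.01, 0.02]), WeightingConfig())
        np.testing.assert_allclose(w.w[:, 0], [0.8, 0.2], atol=1e-12)

    def test_zero_sigma_floored_and_dominant(self):
        w = weights_unbiased(one_sample_preds([0.0, 0.1]), WeightingConfig())
        assert w.w[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert w.w[1, 0] < 1e-13

    def test_minimises_combined_variance_on_simplex_grid(self):
        # dense grid search over 3-member weight simplex
        rng = np.random.default_rng(11)
        steps = np.linspace(0, 1, 101)
        g1, g2 = np.meshgrid(steps, steps)
        keep = g1 + g2 <= 1.0
        grid = np.column_stack([g1[keep], g2[keep], 1.0 - g1[keep] - g2[keep]])
        for _ in range(20):
            sig = rng.uniform(0.01, 0.3, 3)
            p = one_sample_preds(sig, mus=[0.2, 0.5, 0.8])
            w = weights_unbiased(p, WeightingConfig()).w[:, 0]
            ours = np.sum(w**2 * sig**2)
            best_grid = np.min(grid**2 @ sig**2)
            assert ours <= best_grid + 1e-9


class TestNegativeSoftmaxWeights:
    def test_c_zero_is_uniform(self, fig2_preds):
        w = weights_negative_softmax(
            fig2_preds, WeightingConfig(scheme="negative_softmax", c=0.0)
        )
        np.testing.assert_allclose(w.w[:, 0], np.full(5, 0.2), atol=1e-15)

    def test_c_100_matches_termwise_oracle(self, fig2_preds, fig2_sigmas):
        w = weights_negative_softmax(
            fig2_preds, WeightingConfig(scheme="negative_softmax", c=100.0)
        )
        raw = np.exp(-100.0 * fig2_sigmas)
        np.testing.assert_allclose(w.w[:, 0], raw / raw.sum(), atol=1e-12)
        np.testing.assert_allclose(
            w.w[:, 0], [0.1085, 0.1789, 0.1881, 0.2297, 0.2949], atol=1e-4
        )

    def test_huge_c_concentrates_on_minimum_sigma(self, fig2_preds):
        w = weights_negative_softmax(
            fig2_preds, WeightingConfig(scheme="negative_softmax", c=1e6)
        )
        np.testing.assert_allclose(w.w[:, 0], [0, 0, 0, 0, 1], atol=1e-12)

    def test_stabilisation_shift_does_not_change_weights(self):
        # adding a constant to every sigma must leave NS weights unchanged
        # (exp(-c(s+a)) normalises identically to exp(-cs))
        p1 = one_sample_preds([0.01, 0.03, 0.07])
        p2 = one_sample_preds([0.51, 0.53, 0.57])
        cfg = WeightingConfig(scheme="negative_softmax", c=30.0)
        np.testing.assert_allclose(
            weights_negative_softmax(p1, cfg).w,
            weights_negative_softmax(p2, cfg).w,
            atol=1e-12,
        )

    def test_min_sigma_weight_monotone_in_c(self, fig2_preds):
        ws = [
            weights_negative_softmax(
                fig2_preds, WeightingConfig(scheme="negative_softmax", c=c)
            ).w[4, 0]
            for c in (0.0, 1.0, 5.0, 25.0, 100.0, 1000.0)
        ]
        assert all(b > a for a, b in zip(ws, ws[1:]))


class TestKldWeights:
    def test_all_members_at_reference_fall_back_to_uniform(self):
        p = one_sample_preds([0.1, 0.1, 0.1], mus=[0.5, 0.5, 0.5])
        w = weights_kld(p, WeightingConfig(scheme="kld"))
        np.testing.assert_allclose(w.w[:, 0], np.full(3, 1 / 3))

    def test_zero_divergence_member_gets_zero_weight(self):
        p = one_sample_preds([0.01, 0.1], mus=[0.8, 0.5])
        w = weights_kld(p, WeightingConfig(scheme="kld"))
        assert w.w[0, 0] == pytest.approx(1.0)
        assert w.w[1, 0] == pytest.approx(0.0, abs=1e-15)

    def test_two_member_closed_form_ratio(self):
        # raw divergences 6.307585 and 4.818147 -> weights 0.5669, 0.4331
        p = one_sample_preds([0.01, 0.05], mus=[0.8, 0.8])
        w = weights_kld(p, WeightingConfig(scheme="kld"))
        np.testing.assert_allclose(w.w[:, 0], [0.5669, 0.4331], atol=1e-4)


class TestEnsemblePredict:
    def test_uniform_weights_give_arithmetic_mean(self):
        p = one_sample_preds([0.1, 0.1, 0.1], mus=[0.2, 0.4, 0.6])
        ens = soft_vote(p)
        assert ens.mu_ens[0] == pytest.approx(0.4)

    def test_delta_weight_selects_member(self):
        p = one_sample_preds([0.2, 0.1], mus=[0.9, 0.1])
        w = WeightMatrix(p.member_ids, p.sample_ids, np.array([[1.0], [0.0]]))
        ens = ensemble_predict(p, w)
        assert ens.mu_ens[0] == 0.9
        assert ens.var_ens[0] == pytest.approx(0.2**2)

    def test_matches_loop_oracle_on_seeded_instance(self):
        p = make_random_preds(5, 20, seed=99)
        cfg = WeightingConfig(scheme="kld")
        w = weights_kld(p, cfg)
        ens = ensemble_predict(p, w)
        for j in range(20):
            mu = sum(w.w[k, j] * p.mu[k, j] for k in range(5))
            var = sum(w.w[k, j] ** 2 * p.sigma[k, j] ** 2 for k in range(5))
            assert ens.mu_ens[j] == pytest.approx(mu, abs=1e-12)
            assert ens.var_ens[j] == pytest.approx(var, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        p = one_sample_preds([0.1, 0.2])
        other = one_sample_preds([0.1, 0.2, 0.3])
        w = weights_unbiased(other, WeightingConfig())
        with pytest.raises(ValidationError):
            ensemble_predict(p, w)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_in_convex_hull_of_member_means(self, seed):
        p = make_random_preds(4, 6, seed=seed)
        for scheme in ("unbiased", "negative_softmax", "kld"):
            ens = dune(p, WeightingConfig(scheme=scheme, c=17.0))
            assert np.all(ens.mu_ens >= p.mu.min(axis=0) - 1e-12)
            assert np.all(ens.mu_ens <= p.mu.max(axis=0) + 1e-12)
            assert np.all(ens.var_ens >= 0)


class TestWeightMatrixProperties:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_weights_nonnegative_and_sum_to_one(self, seed):
        p = make_random_preds(5, 8, seed=seed)
        for fn, cfg in (
            (weights_unbiased, WeightingConfig()),
            (weights_negative_softmax, WeightingConfig(scheme="negative_softmax", c=40.0)),
            (weights_kld, WeightingConfig(scheme="kld")),
        ):
            w = fn(p, cfg).w
            assert np.all(w >= 0)
            np.testing.assert_allclose(w.sum(axis=0), 1.0, rtol=0, atol=1e-12)

    def test_member_permutation_equivariance(self):
        p = make_random_preds(5, 8, seed=5)
        perm = [3, 0, 4, 1, 2]
        permuted = MemberPredictions(
            tuple(p.member_ids[i] for i in perm),
            p.sample_ids,
            p.mu[perm],
            p.sigma[perm],
        )
        for fn, cfg in (
            (weights_unbiased, WeightingConfig()),
            (weights_negative_softmax, WeightingConfig(scheme="negative_softmax", c=40.0)),
            (weights_kld, WeightingConfig(scheme="kld")),
        ):
            w = fn(p, cfg).w
            wp = fn(permuted, cfg).w
            np.testing.assert_allclose(wp, w[perm], atol=1e-12)


class TestDuneDispatch:
    def test_unknown_scheme_rejected(self):
        with pytest.raises((ValidationError, ValueError)):
            WeightingConfig(scheme="banana")

    def test_ns_c0_equals_soft_vote(self):
        p = make_random_preds(5, 30, seed=2)
        a = dune(p, WeightingConfig(scheme="negative_softmax", c=0.0))
        b = soft_vote(p)
        assert np.array_equal(a.mu_ens, b.mu_ens)
        assert np.array_equal(a.var_ens, b.var_ens)

    def test_ns_huge_c_equals_uncertainty_vote(self):
        p = make_random_preds(5, 30, seed=3)
        a = dune(p, WeightingConfig(scheme="negative_softmax", c=1e6))
        b = uncertainty_vote(p)
        np.testing.assert_allclose(a.mu_ens, b.mu_ens, atol=1e-9)

    def test_kld_three_member_hand_computation(self):
        # members N(0.8, 0.01^2), N(0.8, 0.05^2), N(0.5, 0.1^2) against the
        # N(0.5, 0.1^2) reference: divergences 6.307585, 4.818147, 0
        p = one_sample_preds([0.01, 0.05, 0.1], mus=[0.8, 0.8, 0.5])
        ens = dune(p, WeightingConfig(scheme="kld"))
        w1 = 6.307585 / (6.307585 + 4.818147)
        expected = w1 * 0.8 + (1 - w1) * 0.8
        assert ens.mu_ens[0] == pytest.approx(expected, abs=1e-6)
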