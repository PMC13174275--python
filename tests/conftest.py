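import numpy as np
import pytest

from dune_ensemble import Labels, MemberPredictions


def make_random_preds(n_members: int, n_samples: int, seed: int) -> MemberPredictions:
    rng = np.random.default_rng(seed)
    mu = rng.random((n_members, n_samples))
    sigma = rng.lognormal(mean=np.log(0.02), sigma=0.6, size=(n_members, n_samples))
    return MemberPredictions(
        tuple(f"m{k}" for k in range(n_members)),
        tuple(f"s{j}" for j in range(n_samples)),
        mu,
        sigma,
    )


def make_preds_resolved_minima(seed: int, n_members: int = 5, n_samples: int = 10) -> MemberPredictions:
    """Random grid whose per-sample smallest sigma is unique by at least 1e-4,
    so a finite negative-softmax control parameter of 1e6 fully resolves the
    argmin."""
    rng = np.random.default_rng(seed)
    mu = rng.random((n_members, n_samples))
    sigma = rng.uniform(0.01, 0.2, (n_members, n_samples))
    for j in range(n_samples):
        while np.diff(np.sort(sigma[:, j]))[0] < 1e-4:
            sigma[:, j] = rng.uniform(0.01, 0.2, n_members)
    return MemberPredictions(
        tuple(f"m{k}" for k in range(n_members)),
        tuple(f"s{j}" for j in range(n_samples)),
        mu,
        sigma,
    )


@pytest.fixture
def random_preds():
    """Factory for seeded random prediction grids."""
    return make_random_preds


@pytest.fixture
def fig2_sigmas():
    """The five-member sigma profile used to illustrate negative-softmax weights."""
    return np.array([0.0150, 0.0100, 0.0095, 0.0075, 0.0050])


@pytest.fixture
def fig2_preds(fig2_sigmas):
    mu = np.array([[0.6], [0.7], [0.8], [0.55], [0.9]])
    return MemberPredictions(
        tuple(f"m{k}" for k in range(5)),
        ("s0",),
        mu,
        fig2_sigmas.reshape(5, 1),
    )


@pytest.fixture
def small_labeled():
    """3 members x 4 samples with hand-chosen values and labels."""
    preds = MemberPredictions(
        ("a", "b", "c"),
        ("s1", "s2", "s3", "s4"),
        np.array(
            [
                [0.9, 0.2, 0.7, 0.4],
                [0.8, 0.1, 0.6, 0.3],
                [0.4, 0.3, 0.9, 0.6],
            ]
        ),
        np.array(
            [
                [0.01, 0.02, 0.05, 0.03],
                [0.02, 0.01, 0.04, 0.02],
                [0.08, 0.03, 0.01, 0.05],
            ]
        ),
    )
    labels = Labels(("s1", "s2", "s3", "s4"), np.array([1, 0, 1, 0]))
    return preds, labels
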