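"""Data model for probabilistic ensemble predictions and table I/O.

An ensemble of M probabilistic binary classifiers predicts N samples.  Member
k summarises its prediction for sample x as a Gaussian N(mu_k(x),
sigma_k(x)^2), where mu is the positive-class probability and sigma the
predictive standard deviation (the member's epistemic-uncertainty estimate).
This module holds those (mu, sigma) grids, reads/writes them as long-format
TSV/CSV tables, and aggregates raw Monte-Carlo probability draws into (mu,
sigma) summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "MemberPredictions",
    "Labels",
    "McDraws",
    "read_predictions",
    "write_predictions",
    "read_labels",
    "write_labels",
    "read_mc_draws",
    "aggregate_mc_samples",
]

TableFormat = Literal["tsv", "csv"]

#: decimal significant digits used when serialising floats; 17 guarantees a
#: bit-exact binary64 round trip through text
_SIG_DIGITS = 17


class ValidationError(ValueError):
    """Raised when input data violates a documented contract."""


def _sep(fmt: str) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    raise ValidationError(f"unknown table format {fmt!r}; expected 'tsv' or 'csv'")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class MemberPredictions:
    """Gaussian predictive parameters of an M-member ensemble on N samples.

    Attributes
    ----------
    member_ids : tuple of str
        Ordered member identifiers (length M).
    sample_ids : tuple of str
        Ordered sample identifiers (length N).
    mu : ndarray, shape (M, N)
        Predicted positive-class probabilities, in [0, 1].
    sigma : ndarray, shape (M, N)
        Predictive standard deviations, >= 0.
    """

    member_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", tuple(str(m) for m in self.member_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        M, N = len(self.member_ids), len(self.sample_ids)
        if M < 1 or N < 1:
            raise ValidationError("need at least one member and one sample")
        if mu.shape != (M, N) or sigma.shape != (M, N):
            raise ValidationError(
                f"mu/sigma shape {mu.shape}/{sigma.shape} does not match (M={M}, N={N})"
            )
        _check_unique(self.member_ids, "member_id")
        _check_unique(self.sample_ids, "sample_id")
        if not np.all(np.isfinite(mu)) or np.any(mu < 0.0) or np.any(mu > 1.0):
            raise ValidationError("all mu must be finite and within [0, 1]")
        if not np.all(np.isfinite(sigma)) or np.any(sigma < 0.0):
            raise ValidationError("all sigma must be finite and >= 0")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MemberPredictions):
            return NotImplemented
        return (
            self.member_ids == other.member_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.mu, other.mu)
            and np.array_equal(self.sigma, other.sigma)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class Labels:
    """Binary ground-truth labels, aligned by sample_id."""

    sample_ids: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        y = np.asarray(self.y)
        if y.ndim != 1 or len(y) != len(self.sample_ids):
            raise ValidationError("labels must be a 1-D vector aligned with sample_ids")
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("labels must be strictly in {0, 1}")
        object.__setattr__(self, "y", y.astype(np.int64))
        _check_unique(self.sample_ids, "sample_id")

    def aligned_to(self, sample_ids: tuple[str, ...]) -> np.ndarray:
        """Return the label vector reordered to ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"labels missing for sample_ids {missing[:5]}")
        return self.y[[index[s] for s in sample_ids]]


@dataclass(frozen=True)
class McDraws:
    """Raw Monte-Carlo probability draws, shape (M members, N samples, S draws)."""

    member_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    draws: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", tuple(str(m) for m in self.member_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        draws = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", draws)
        M, N = len(self.member_ids), len(self.sample_ids)
        if draws.ndim != 3 or draws.shape[:2] != (M, N):
            raise ValidationError(f"draws must have shape (M={M}, N={N}, S); got {draws.shape}")
        if draws.shape[2] < 2:
            raise ValidationError("cannot estimate spread: need at least S=2 draws per cell")
        if np.any(draws < 0.0) or np.any(draws > 1.0):
            raise ValidationError("all draws must lie in [0, 1]")
        _check_unique(self.member_ids, "member_id")
        _check_unique(self.sample_ids, "sample_id")

    @property
    def n_draws(self) -> int:
        return int(self.draws.shape[2])


def _first_appearance(values) -> list:
    # dict preserves insertion order; dedupes while keeping file order
    return list(dict.fromkeys(values))


def read_predictions(path: str | Path, format: TableFormat = "tsv") -> MemberPredictions:
    """Read a long-format prediction table into a complete (M, N) grid.

    The file must carry the header ``sample_id member_id mu sigma`` and one
    row per (sample, member) pair.  Member and sample order follow first
    appearance in the file, so on-disk row order never changes the grid
    layout downstream modules see.

    Raises
    ------
    ValidationError
        If a (sample, member) cell is missing, duplicated, or a value is out
        of range (the error names the offending pair or file line).
    """
    df = pd.read_csv(path, sep=_sep(format), dtype={"sample_id": str, "member_id": str}, float_precision="round_trip")
    required = ["sample_id", "member_id", "mu", "sigma"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"prediction table missing columns {missing_cols}")

    # +2: header line plus 1-based counting
    for row in df.itertuples():
        line = row.Index + 2
        if not (0.0 <= row.mu <= 1.0):
            raise ValidationError(f"line {line}: mu={row.mu} outside [0, 1]")
        if row.sigma < 0.0:
            raise ValidationError(f"line {line}: sigma={row.sigma} < 0")

    sample_ids = _first_appearance(df["sample_id"])
    member_ids = _first_appearance(df["member_id"])
    s_index = {s: j for j, s in enumerate(sample_ids)}
    m_index = {m: i for i, m in enumerate(member_ids)}
    M, N = len(member_ids), len(sample_ids)

    mu = np.full((M, N), np.nan)
    sigma = np.full((M, N), np.nan)
    for row in df.itertuples():
        i, j = m_index[row.member_id], s_index[row.sample_id]
        if not np.isnan(mu[i, j]):
            raise ValidationError(
                f"duplicate cell for (sample {row.sample_id!r}, member {row.member_id!r})"
            )
        mu[i, j] = row.mu
        sigma[i, j] = row.sigma

    holes = np.argwhere(np.isnan(mu))
    if holes.size:
        i, j = holes[0]
        raise ValidationError(
            "incomplete grid: missing row for "
            f"(sample {sample_ids[j]!r}, member {member_ids[i]!r})"
        )
    return MemberPredictions(tuple(member_ids), tuple(sample_ids), mu, sigma)


def write_predictions(
    preds: MemberPredictions, path: str | Path, format: TableFormat = "tsv"
) -> None:
    """Write a prediction grid as a long-format table (bit-exact round trip)."""
    rows = []
    for j, s in enumerate(preds.sample_ids):
        for i, m in enumerate(preds.member_ids):
            rows.append((s, m, f"{preds.mu[i, j]:.{_SIG_DIGITS}g}",
                         f"{preds.sigma[i, j]:.{_SIG_DIGITS}g}"))
    df = pd.DataFrame(rows, columns=["sample_id", "member_id", "mu", "sigma"])
    df.to_csv(path, sep=_sep(format), index=False)


def read_labels(path: str | Path, format: TableFormat = "tsv") -> Labels:
    """Read a ``sample_id label`` table with labels in {0, 1}."""
    df = pd.read_csv(path, sep=_sep(format), dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ValidationError("label table must have columns sample_id, label")
    return Labels(tuple(df["sample_id"]), df["label"].to_numpy())


def write_labels(labels: Labels, path: str | Path, format: TableFormat = "tsv") -> None:
    df = pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.y})
    df.to_csv(path, sep=_sep(format), index=False)


def read_mc_draws(path: str | Path, format: TableFormat = "tsv") -> McDraws:
    """Read a ``sample_id member_id draw_index p`` table into an (M, N, S) cube."""
    df = pd.read_csv(path, sep=_sep(format), dtype={"sample_id": str, "member_id": str}, float_precision="round_trip")
    required = ["sample_id", "member_id", "draw_index", "p"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"draw table missing columns {missing_cols}")
    sample_ids = _first_appearance(df["sample_id"])
    member_ids = _first_appearance(df["member_id"])
    draw_ids = sorted(df["draw_index"].unique())
    s_index = {s: j for j, s in enumerate(sample_ids)}
    m_index = {m: i for i, m in enumerate(member_ids)}
    d_index = {d: k for k, d in enumerate(draw_ids)}
    cube = np.full((len(member_ids), len(sample_ids), len(draw_ids)), np.nan)
    for row in df.itertuples():
        cube[m_index[row.member_id], s_index[row.sample_id], d_index[row.draw_index]] = row.p
    if np.isnan(cube).any():
        raise ValidationError("incomplete draw cube: some (sample, member, draw) cells missing")
    return McDraws(tuple(member_ids), tuple(sample_ids), cube)


def write_mc_draws(draws: McDraws, path: str | Path, format: TableFormat = "tsv") -> None:
    rows = []
    for j, s in enumerate(draws.sample_ids):
        for i, m in enumerate(draws.member_ids):
            for k in range(draws.n_draws):
                rows.append((s, m, k, f"{draws.draws[i, j, k]:.{_SIG_DIGITS}g}"))
    df = pd.DataFrame(rows, columns=["sample_id", "member_id", "draw_index", "p"])
    df.to_csv(path, sep=_sep(format), index=False)


def aggregate_mc_samples(draws: McDraws) -> MemberPredictions:
    """Summarise S Monte-Carlo probability draws per cell into (mu, sigma).

    mu is the arithmetic mean and sigma the population standard deviation
    (denominator S, not S-1) of the draws — the plain second moment of the
    predictive sample, which keeps sigma = 0 attainable for constant draws.
    mu is clipped into [0, 1] only to absorb floating-point round-off.
    """
    if draws.n_draws < 2:
        raise ValidationError("cannot estimate spread from fewer than 2 draws")
    mu = draws.draws.mean(axis=2)
    sigma = draws.draws.std(axis=2)  # ddof=0: population std
    return MemberPredictions(
        draws.member_ids, draws.sample_ids, np.clip(mu, 0.0, 1.0), sigma
    )
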