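"""Bandt-Pompe ordinal symbolization of numeric time series.

A time series is scanned with overlapping embedding vectors
``(x[s-(d-1)τ], ..., x[s-τ], x[s])`` of dimension ``d`` and delay ``τ``.
Each vector is mapped to the permutation ``π = (r0, ..., r_{d-1})`` of the
time offsets that orders the values descendingly,

    x[s - r0 τ] ≥ x[s - r1 τ] ≥ ... ≥ x[s - r_{d-1} τ],

so offset 0 is the most recent sample and offset d-1 the oldest.  Equal
values are ordered by temporal position with the earlier sample (larger
offset) first, which makes constant vectors map deterministically to
``(d-1, ..., 1, 0)``.  Counting permutation occurrences over all
``N - (d-1)τ`` vectors yields the ordinal-pattern probability distribution
``P = {p(π_i), i = 1..d!}`` on which permutation entropy and statistical
complexity are built.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrdinalConfig",
    "OrdinalPattern",
    "OrdinalDistribution",
    "OrdinalWarning",
    "symbolize_window",
    "ordinal_distribution",
    "pattern_index",
    "index_to_pattern",
]


class OrdinalWarning(UserWarning):
    """Raised when the series is too short for reliable pattern statistics."""


@dataclass(frozen=True)
class OrdinalConfig:
    """Embedding dimension ``d`` and delay ``tau`` (both in samples).

    The number of accessible symbols is ``d!``; d between 3 and 7 is the
    practical range, and the series length should satisfy ``N >> d!``.
    """

    d: int = 6
    tau: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.d, (int, np.integer)) or self.d < 2:
            raise ValueError(f"embedding dimension d must be an integer >= 2, got {self.d}")
        if not isinstance(self.tau, (int, np.integer)) or self.tau < 1:
            raise ValueError(f"embedding delay tau must be an integer >= 1, got {self.tau}")

    @property
    def n_patterns(self) -> int:
        """Number of accessible ordinal symbols, d!."""
        return math.factorial(self.d)

    @property
    def span(self) -> int:
        """Samples covered by one embedding vector: (d-1)·tau + 1."""
        return (self.d - 1) * self.tau + 1


@dataclass(frozen=True)
class OrdinalPattern:
    """A single ordinal symbol: the offset permutation and its integer rank."""

    ranks: tuple[int, ...]
    index: int

    @property
    def d(self) -> int:
        return len(self.ranks)


@dataclass
class OrdinalDistribution:
    """Probability distribution over the d! ordinal patterns of a series."""

    d: int
    tau: int
    counts: np.ndarray
    probs: np.ndarray
    n_vectors: int
    n_skipped: int = 0

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.d)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.counts.shape != (self.n_patterns,):
            raise ValueError("counts must have length d!")
        if int(self.counts.sum()) != self.n_vectors:
            raise ValueError("counts must sum to n_vectors")
        if self.n_vectors > 0 and abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must sum to 1")


_FACTORIALS = [math.factorial(k) for k in range(21)]


def pattern_index(pattern: OrdinalPattern | tuple[int, ...]) -> int:
    """Lexicographic rank of a rank-permutation among all d! permutations."""
    ranks = pattern.ranks if isinstance(pattern, OrdinalPattern) else tuple(pattern)
    d = len(ranks)
    if sorted(ranks) != list(range(d)):
        raise ValueError(f"{ranks!r} is not a permutation of 0..{d - 1}")
    idx = 0
    for i, r in enumerate(ranks):
        smaller_later = sum(1 for r2 in ranks[i + 1 :] if r2 < r)
        idx += smaller_later * _FACTORIALS[d - 1 - i]
    return idx


def index_to_pattern(i: int, d: int) -> OrdinalPattern:
    """Inverse of :func:`pattern_index` (lexicographic unranking)."""
    m = math.factorial(d)
    if not 0 <= i < m:
        raise ValueError(f"index {i} out of range for d={d} (0..{m - 1})")
    avail = list(range(d))
    ranks = []
    rem = i
    for pos in range(d):
        f = _FACTORIALS[d - 1 - pos]
        j, rem = divmod(rem, f)
        ranks.append(avail.pop(j))
    return OrdinalPattern(ranks=tuple(ranks), index=i)


def symbolize_window(window, config: OrdinalConfig) -> OrdinalPattern:
    """Ordinal pattern of one already-extracted embedding vector.

    ``window`` holds the d values in time order, oldest first:
    ``(x[s-(d-1)τ], ..., x[s])``.  Returns the permutation of time offsets
    sorted by descending value, ties resolved in favor of the earlier
    (larger-offset) sample.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.shape[0] != config.d:
        raise ValueError(f"window must contain exactly d={config.d} values, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise FloatingPointError("window contains non-finite values; cannot symbolize")
    # window position j has time offset r = d-1-j; stable argsort on -value
    # orders ties by ascending j, i.e. descending offset (earlier sample first).
    order = np.argsort(-w, kind="stable")
    ranks = tuple(int(config.d - 1 - j) for j in order)
    return OrdinalPattern(ranks=ranks, index=pattern_index(ranks))


def _embed(x: np.ndarray, d: int, tau: int) -> np.ndarray:
    """All embedding vectors of x as an (n_vectors, d) matrix, time order."""
    span = (d - 1) * tau + 1
    if x.shape[0] < span:
        raise ValueError(
            f"series of length {x.shape[0]} is shorter than one embedding vector (span {span})"
        )
    return np.lib.stride_tricks.sliding_window_view(x, span)[:, ::tau]


def _pattern_codes(vectors: np.ndarray, d: int) -> np.ndarray:
    """Vectorized lexicographic pattern index for each row of ``vectors``."""
    # ranks[i] = offset of the i-th largest value; window column j has offset d-1-j
    order = np.argsort(-vectors, axis=1, kind="stable")
    ranks = d - 1 - order
    # Lehmer code: c_i = #{j > i : ranks[j] < ranks[i]}
    cmp = ranks[:, :, None] > ranks[:, None, :]
    upper = np.triu(np.ones((d, d), dtype=bool), k=1)
    c = (cmp & upper[None, :, :]).sum(axis=2)
    weights = np.array([_FACTORIALS[d - 1 - i] for i in range(d)], dtype=np.int64)
    return c @ weights


def ordinal_distribution(
    series,
    config: OrdinalConfig,
    chunk_size: int = 1_000_000,
) -> OrdinalDistribution:
    """Estimate the Bandt-Pompe distribution of a series.

    The series is processed in overlapping chunks so hour-long recordings at
    typical hydrophone rates are symbolized in bounded memory.  Embedding
    vectors containing NaN are skipped and tallied in ``n_skipped`` rather
    than imputed, so ``probs`` stays normalized over valid vectors only.
    """
    x = np.asarray(series, dtype=float).ravel()
    d, tau = config.d, config.tau
    m = config.n_patterns
    if x.size < config.span:
        raise ValueError(
            f"series of length {x.size} is too short for d={d}, tau={tau} "
            f"(needs at least {config.span} samples)"
        )
    if np.all(np.isnan(x)):
        raise ValueError("series is all-NaN")
    if x.size < 100 * m:
        warnings.warn(
            f"series length N={x.size} < 100·d! = {100 * m}; the length N of the "
            "series should greatly exceed d! for reliable pattern statistics",
            OrdinalWarning,
            stacklevel=2,
        )

    counts = np.zeros(m, dtype=np.int64)
    n_skipped = 0
    overlap = config.span - 1
    step = max(chunk_size, 2 * config.span)
    start = 0
    while start < x.size - overlap:
        chunk = x[start : start + step + overlap]
        vectors = _embed(chunk, d, tau)
        valid = np.all(np.isfinite(vectors), axis=1)
        n_skipped += int((~valid).sum())
        if valid.any():
            codes = _pattern_codes(vectors[valid], d)
            counts += np.bincount(codes, minlength=m)
        start += step
    n_vectors = int(counts.sum())
    if n_vectors == 0:
        raise ValueError("no valid (finite) embedding vectors in series")
    probs = counts / n_vectors
    return OrdinalDistribution(
        d=d, tau=tau, counts=counts, probs=probs, n_vectors=n_vectors, n_skipped=n_skipped
    )
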