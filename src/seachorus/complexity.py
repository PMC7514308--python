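"""Permutation entropy, Jensen-Shannon statistical complexity and the C-H plane.

Given an ordinal-pattern distribution P over M = d! symbols, the quantifiers

    H_s[P] = S[P] / ln M                      (normalized permutation entropy)
    C[P]   = Q_J[P, P_e] · H_s[P]             (statistical complexity)

where S is Shannon entropy in nats, P_e the uniform distribution, and
Q_J = Q0 · J[P, P_e] the Jensen-Shannon disequilibrium normalized so that
Q_J = 1 at a delta distribution.  Periodic dynamics sit at low H / high C,
uncorrelated noise at high H / low C; for every H there is a band of
attainable complexities bounded by the C_min / C_max limit curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ordinal import OrdinalConfig, OrdinalDistribution, ordinal_distribution

__all__ = [
    "CHPoint",
    "PlaneReference",
    "shannon_entropy",
    "normalized_entropy",
    "jensen_shannon_divergence",
    "max_jsd",
    "disequilibrium",
    "statistical_complexity",
    "global_complexity",
    "limit_curves",
]


@dataclass(frozen=True)
class CHPoint:
    """One point on the complexity-entropy plane."""

    H: float
    C: float
    d: int
    n_vectors: int = 0


@dataclass
class PlaneReference:
    """Constants and boundary curves of the C-H plane for one dimension d.

    ``min_curve`` and ``max_curve`` are (H, C) polylines sorted by H; both
    touch C = 0 at H = 0 and H = 1.
    """

    d: int
    M: int
    S_max: float
    Q0: float
    min_curve: np.ndarray  # shape (n, 2): columns H, C
    max_curve: np.ndarray

    def c_min(self, h) -> np.ndarray:
        return np.interp(h, self.min_curve[:, 0], self.min_curve[:, 1])

    def c_max(self, h) -> np.ndarray:
        return np.interp(h, self.max_curve[:, 0], self.max_curve[:, 1])

    def contains(self, points, tol: float = 1e-3) -> np.ndarray:
        """Boolean mask: which (H, C) points lie within [C_min - tol, C_max + tol]."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h, c = pts[:, 0], pts[:, 1]
        return (c >= self.c_min(h) - tol) & (c <= self.c_max(h) + tol)


def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any(p < -1e-12):
        raise ValueError("probability vector has negative entries")
    s = p.sum()
    if not np.isfinite(s) or abs(s - 1.0) > 1e-9:
        raise ValueError(f"probability vector sums to {s}, not 1")
    return np.clip(p, 0.0, None)


def shannon_entropy(p) -> float:
    """S[P] = -Σ p_i ln p_i in nats, with 0·ln 0 = 0."""
    p = _validate_probs(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def normalized_entropy(p) -> float:
    """H_s[P] = S[P] / ln M, in [0, 1]."""
    p = _validate_probs(p)
    m = p.size
    if m < 2:
        raise ValueError("need at least 2 states to normalize entropy")
    return shannon_entropy(p) / math.log(m)


def jensen_shannon_divergence(p, q) -> float:
    """J[P, Q] = S[(P+Q)/2] - S[P]/2 - S[Q]/2 in nats; symmetric, >= 0."""
    p = _validate_probs(p)
    q = _validate_probs(q)
    if p.size != q.size:
        raise ValueError(f"length mismatch: {p.size} vs {q.size}")
    return shannon_entropy((p + q) / 2.0) - shannon_entropy(p) / 2.0 - shannon_entropy(q) / 2.0


def max_jsd(m: int) -> float:
    """Maximum of J[P, P_e] over all P on M states, attained at a delta.

    Closed form: -1/2 [ ((M+1)/M) ln(M+1) - 2 ln(2M) + ln M ].
    """
    if m < 2:
        raise ValueError("need M >= 2")
    return -0.5 * (((m + 1) / m) * math.log(m + 1) - 2 * math.log(2 * m) + math.log(m))


def disequilibrium(p, d: int | None = None) -> float:
    """Normalized Jensen-Shannon disequilibrium Q_J[P, P_e] in [0, 1]."""
    p = _validate_probs(p)
    m = p.size
    if d is not None and math.factorial(d) != m:
        raise ValueError(f"probability vector of length {m} does not match d={d} (d! = {math.factorial(d)})")
    pe = np.full(m, 1.0 / m)
    return jensen_shannon_divergence(p, pe) / max_jsd(m)


def statistical_complexity(p, d: int | None = None) -> float:
    """C[P] = Q_J[P, P_e] · H_s[P]."""
    p = _validate_probs(p)
    return disequilibrium(p, d) * normalized_entropy(p)


def global_complexity(
    series, config: OrdinalConfig | None = None
) -> CHPoint:
    """Compute the (H, C) point of a raw time series.

    Symbolizes with the Bandt-Pompe scheme (default d = 6, τ = 1) and
    evaluates normalized permutation entropy and statistical complexity of
    the resulting ordinal distribution.
    """
    cfg = config or OrdinalConfig()
    dist = ordinal_distribution(series, cfg)
    return ch_point(dist)


def ch_point(dist: OrdinalDistribution) -> CHPoint:
    """(H, C) of an already-estimated ordinal distribution."""
    p = dist.probs
    return CHPoint(
        H=normalized_entropy(p),
        C=statistical_complexity(p),
        d=dist.d,
        n_vectors=dist.n_vectors,
    )


def _family_hc(m: int, p_free: np.ndarray, n_zero: int, q0: float) -> tuple[np.ndarray, np.ndarray]:
    """(H, C) of distributions with ``n_zero`` empty states, one free
    component ``p_free`` and the remaining mass split equally.

    All quantities evaluate in closed form, so the boundary families can be
    sampled densely even for M = 720.
    """
    k = m - n_zero  # occupied states
    p = np.asarray(p_free, dtype=float)
    rest = (1.0 - p) / (k - 1)

    def plogp(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log(v[nz])
        return out

    s = -(plogp(p) + (k - 1) * plogp(rest))
    # mixture with the uniform distribution over all M states
    a = (p + 1.0 / m) / 2.0
    b = (rest + 1.0 / m) / 2.0
    c = 1.0 / (2.0 * m)
    s_mix = -(plogp(a) + (k - 1) * plogp(b) + n_zero * (c * math.log(c)))
    j = s_mix - s / 2.0 - math.log(m) / 2.0
    h = s / math.log(m)
    return h, q0 * j * h


def limit_curves(d: int, n_grid: int = 2000) -> PlaneReference:
    """C_min / C_max boundary curves of the C-H plane for dimension d.

    C_min comes from the one-parameter family {p, (1-p)/(M-1), ...} with
    p ∈ [1/M, 1].  C_max is the upper envelope over the families that set n
    components to zero (n = 0..M-2) and split the rest as one free component
    plus equal shares.  Curves are sampled on a uniform parameter grid and
    re-gridded in H by linear interpolation.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    if n_grid < 100:
        raise ValueError("n_grid must be >= 100")
    m = math.factorial(d)
    if m > 50_000:
        raise ValueError(
            f"d={d} gives M=d!={m} states; boundary envelope over M-1 families is "
            "impractical at this size — use d <= 8 or precompute curves externally"
        )
    q0 = 1.0 / max_jsd(m)

    # lower bound: p from 1/M (uniform, H=1) to 1 (delta, H=0)
    p_lo = np.linspace(1.0 / m, 1.0, n_grid)
    h_lo, c_lo = _family_hc(m, p_lo, 0, q0)
    order = np.argsort(h_lo)
    min_curve = np.column_stack([h_lo[order], c_lo[order]])

    # upper bound: envelope over n-zero families, p in [0, 1/(M-n)];
    # family n covers H in [ln(M-n-1), ln(M-n)]/ln M so together they tile (0, 1]
    h_grid = np.linspace(0.0, 1.0, n_grid)
    c_env = np.zeros(n_grid)
    filled = np.zeros(n_grid, dtype=bool)
    # quadratic spacing concentrates samples near p = 0 where H varies fastest
    u2 = np.linspace(0.0, 1.0, n_grid) ** 2
    for n_zero in range(m - 1):
        k = m - n_zero
        if k < 2:
            continue
        p = u2 / k
        h, c = _family_hc(m, p, n_zero, q0)
        idx = np.clip(np.round(h * (n_grid - 1)).astype(int), 0, n_grid - 1)
        np.maximum.at(c_env, idx, c)
        filled[idx] = True
    # fill grid cells no family sample landed in by interpolating the envelope
    if not filled.all():
        c_env[~filled] = np.interp(h_grid[~filled], h_grid[filled], c_env[filled])
    # both boundary curves reach C = 0 exactly at the entropy extremes
    c_env[0] = 0.0
    c_env[-1] = 0.0
    max_curve = np.column_stack([h_grid, c_env])

    return PlaneReference(
        d=d, M=m, S_max=math.log(m), Q0=q0, min_curve=min_curve, max_curve=max_curve
    )
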