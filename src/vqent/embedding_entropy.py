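"""Delay-vector embedding and the sample-based entropy estimators.

A windowed signal of ``N`` samples is unfolded into ``Q = N - M`` delay
vectors of length ``M`` (the symbolic state space). Sample entropy is
``-ln(pi(M+1)/pi(M))`` where ``pi`` is the proportion of ordered vector
pairs (self-pairs excluded) whose Chebyshev distance falls below the
tolerance; fuzzy entropy replaces the hard count with a Gaussian
membership of that distance. The tolerance is expressed as a multiple
``rho`` of the signal's standard deviation, which makes both estimators
invariant to affine rescaling of the signal. The reference deviation is
that of the *measured data*: an estimator called on a bare window uses
the window's own deviation, but sliding-window time-courses (see
:mod:`vqent.erds`) fix the tolerance from the whole trial so that an
amplitude drop inside one window is visible to the estimator rather
than normalized away.

Note the ``Q = N - M`` convention (not the more common ``N - M + 1``):
the last sample of the window never starts a vector. With window lengths
in the hundreds the difference is immaterial, but the convention is kept
consistently so that pattern counts at dimensions M and M+1 refer to the
same construction rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSet",
    "EntropyParams",
    "PatternCount",
    "embed",
    "pattern_count",
    "sample_entropy",
    "fuzzy_entropy",
]

ESTIMATORS = ("sampen", "fuzzyen", "vqent")


@dataclass(frozen=True)
class EntropyParams:
    """Estimator configuration: embedding dimension and relative tolerance.

    ``rho`` multiplies the per-window standard deviation to give the
    absolute tolerance; ``0.1``-``0.3`` is the usual working range.
    """

    M: int = 2
    rho: float = 0.3
    estimator: str = "vqent"

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("embedding dimension M must be >= 1")
        if self.rho <= 0:
            raise ValueError("tolerance rho must be positive")
        if self.estimator not in ESTIMATORS:
            raise ValueError(
                f"estimator must be one of {ESTIMATORS}, got {self.estimator!r}"
            )


@dataclass(frozen=True)
class EmbeddingSet:
    """Delay-vector matrix: ``Q x M`` contiguous slices of a source window."""

    vectors: np.ndarray
    M: int
    source_window: np.ndarray = field(repr=False)

    @property
    def Q(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class PatternCount:
    """Match probabilities at dimensions M and M+1."""

    pi_M: float
    pi_M1: float


def embed(window: np.ndarray, M: int) -> EmbeddingSet:
    """Unfold a window into its ``Q = N - M`` delay vectors of length M."""
    window = np.asarray(window, dtype=float).ravel()
    n = window.size
    if M < 1:
        raise ValueError("M must be >= 1")
    if n <= M:
        raise ValueError(f"window length {n} must exceed M={M}")
    q = n - M
    vectors = sliding_window_view(window, M)[:q]
    return EmbeddingSet(vectors=vectors, M=M, source_window=window)


def _pair_stats(vectors: np.ndarray, rho_abs: float, distance: str) -> float:
    """Mean match indicator (chebyshev) or membership (fuzzy) over ordered
    pairs q != q'."""
    q = vectors.shape[0]
    if q < 2:
        raise ValueError("need at least 2 delay vectors")
    d = cdist(vectors, vectors, metric="chebyshev")
    mask = ~np.eye(q, dtype=bool)
    if distance == "chebyshev":
        return float(np.count_nonzero(d[mask] < rho_abs)) / (q * (q - 1))
    if distance == "fuzzy":
        # Gaussian membership of the Chebyshev distance
        return float(np.mean(np.exp(-((d[mask] / rho_abs) ** 2))))
    raise ValueError(f"unknown distance {distance!r}")


def pattern_count(
    emb: EmbeddingSet, rho_abs: float, distance: str = "chebyshev"
) -> PatternCount:
    """Match probabilities at dimension M and, by re-embedding the source
    window, at M+1.

    ``rho_abs`` is an absolute tolerance in signal units.
    """
    if rho_abs <= 0:
        raise ValueError("rho_abs must be positive")
    n = emb.source_window.size
    if n < emb.M + 3:
        raise ValueError(
            f"window length {n} too short for M+1 pattern counting at M={emb.M}"
        )
    pi_m = _pair_stats(emb.vectors, rho_abs, distance)
    emb1 = embed(emb.source_window, emb.M + 1)
    pi_m1 = _pair_stats(emb1.vectors, rho_abs, distance)
    return PatternCount(pi_M=pi_m, pi_M1=pi_m1)


def _resolve_tolerance(
    window: np.ndarray, params: EntropyParams, rho_abs: float | None
) -> float:
    if rho_abs is not None:
        if rho_abs < 0:
            raise ValueError("rho_abs must be non-negative")
        return float(rho_abs)
    return params.rho * float(np.std(window))


def sample_entropy(
    window: np.ndarray, params: EntropyParams, rho_abs: float | None = None
) -> float:
    """Sample entropy (nats) of a window.

    The tolerance is ``params.rho`` times the window's standard deviation
    unless an absolute tolerance ``rho_abs`` (signal units) is supplied,
    as sliding-window analyses do to keep it fixed across windows.

    A constant window is perfectly regular and returns 0. When no pair
    matches at dimension M+1 the ratio is undefined and NaN is returned
    (logged); downstream time-courses treat such windows as missing.
    """
    window = np.asarray(window, dtype=float).ravel()
    tol = _resolve_tolerance(window, params, rho_abs)
    if tol == 0.0:
        return 0.0
    counts = pattern_count(embed(window, params.M), tol, "chebyshev")
    if counts.pi_M1 == 0.0 or counts.pi_M == 0.0:
        logger.warning(
            "sample_entropy: zero pattern count (pi_M=%g, pi_M1=%g); NaN",
            counts.pi_M,
            counts.pi_M1,
        )
        return float("nan")
    return float(-np.log(counts.pi_M1 / counts.pi_M))


def fuzzy_entropy(
    window: np.ndarray, params: EntropyParams, rho_abs: float | None = None
) -> float:
    """Fuzzy entropy (nats): Gaussian-membership variant of sample entropy.

    Memberships are strictly positive, so the estimate is always finite.
    Tolerance semantics are as in :func:`sample_entropy`.
    """
    window = np.asarray(window, dtype=float).ravel()
    tol = _resolve_tolerance(window, params, rho_abs)
    if tol == 0.0:
        return 0.0
    counts = pattern_count(embed(window, params.M), tol, "fuzzy")
    return float(-np.log(counts.pi_M1 / counts.pi_M))
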