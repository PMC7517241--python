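"""Vector-quantized entropy (VQEnt) of a windowed signal.

Instead of counting template matches among all ``Q`` delay vectors, the
window's delay vectors are compressed into a small codebook of ``Q' <= Q``
code vectors by a single greedy online pass: the first vector seeds the
codebook and a later vector is admitted only if it lies farther than the
tolerance from every code admitted so far. A one-pass probabilistic model
is then fitted over the codes:

1. membership: Gaussian similarity of each delay vector to each code,
   normalized per vector (a row-stochastic soft assignment);
2. per-code moments: membership-weighted mean ``mu`` and scalar variance
   ``sigma^2`` of the delay vectors;
3. likelihood of the data under each code: mean isotropic-Gaussian
   similarity of the delay vectors to ``(mu, sigma^2)``;
4. prior of each code: its mean membership;
5. posterior over codes by Bayes' rule.

The VQEnt estimate is the Shannon entropy (nats) of that posterior; it is
bounded by ``ln Q'``. A strong mu rhythm makes the trajectory revisit few
codes with a peaked posterior (low entropy), so the contralateral entropy
time-course dips during motor imagery just as band power does.

The codebook admission rule compares Euclidean distance to the tolerance
``rho_abs``, which together with the sigma-relative tolerance makes the
estimate invariant under amplitude rescaling. Set
``squared_tolerance=True`` to compare the squared distance against
``rho_abs`` instead (an alternative reading of the admission rule; not
scale-invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding_entropy import EmbeddingSet, EntropyParams, embed

logger = logging.getLogger(__name__)

__all__ = ["VQModel", "build_codebook", "fit_vq_model", "vq_model", "vq_entropy"]

_SIGMA2_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class VQModel:
    """Fitted codebook model: codes, soft assignments, moments, posterior."""

    codebook: np.ndarray  # Q' x M
    rho_abs: float
    membership: np.ndarray  # Q x Q', rows sum to 1
    mu: np.ndarray  # Q' x M
    sigma2: np.ndarray  # Q'
    prior: np.ndarray  # Q', sums to 1
    likelihood: np.ndarray  # Q'
    posterior: np.ndarray  # Q', sums to 1

    @property
    def n_codes(self) -> int:
        return self.codebook.shape[0]

    def entropy(self) -> float:
        """Shannon entropy (nats) of the posterior over codes."""
        p = self.posterior[self.posterior > 0]
        return float(-np.sum(p * np.log(p)))


def _admission_threshold(rho_abs: float, squared_tolerance: bool) -> float:
    # admission compares squared Euclidean distance to this value
    return rho_abs if squared_tolerance else rho_abs**2


def build_codebook(
    emb: EmbeddingSet, rho_abs: float, squared_tolerance: bool = False
) -> np.ndarray:
    """Greedy online codebook: admit a vector iff it is farther than the
    tolerance from every code admitted so far.

    Deterministic in the input order (vectors are visited q = 1..Q). The
    result covers the input: every rejected vector is within tolerance of
    at least one code, and admitted codes are pairwise farther apart than
    the tolerance.
    """
    if rho_abs <= 0:
        raise ValueError("rho_abs must be positive")
    x = emb.vectors
    if x.shape[0] < 1:
        raise ValueError("empty embedding")
    thr = _admission_threshold(rho_abs, squared_tolerance)
    codes = [x[0]]
    code_arr = x[:1]
    for q in range(1, x.shape[0]):
        d2 = ((code_arr - x[q]) ** 2).sum(axis=1)
        if np.all(d2 > thr):
            codes.append(x[q])
            code_arr = np.asarray(codes)
    return np.asarray(codes, dtype=float)


def fit_vq_model(
    emb: EmbeddingSet,
    codebook: np.ndarray,
    rho_abs: float,
) -> VQModel:
    """One-pass Gaussian-similarity model over a fitted codebook.

    The Gaussian similarity bandwidth is ``rho_abs``, the only scale
    parameter of the construction. Degenerate per-code variances (all
    soft mass on one point) are floored at ``1e-12 * rho_abs^2``.
    """
    x = emb.vectors
    codebook = np.atleast_2d(np.asarray(codebook, dtype=float))
    if codebook.shape[1] != x.shape[1]:
        raise ValueError("codebook dimensionality does not match embedding")
    d2 = cdist(x, codebook, metric="sqeuclidean")
    gamma = np.exp(-d2 / (2.0 * rho_abs**2))
    row_sums = gamma.sum(axis=1, keepdims=True)
    # every input is within rho_abs of a code, so rows cannot vanish;
    # guard anyway against extreme underflow
    row_sums[row_sums == 0.0] = 1.0
    membership = gamma / row_sums

    weight = membership.sum(axis=0)  # total soft mass per code
    weight_safe = np.where(weight > 0, weight, 1.0)
    mu = (membership.T @ x) / weight_safe[:, None]
    dev2 = cdist(x, mu, metric="sqeuclidean")
    sigma2 = (membership * dev2).sum(axis=0) / weight_safe
    floor = _SIGMA2_FLOOR_REL * rho_abs**2
    degenerate = sigma2 < floor
    if np.any(degenerate):
        logger.warning(
            "fit_vq_model: %d degenerate code variance(s) floored",
            int(degenerate.sum()),
        )
        sigma2 = np.where(degenerate, floor, sigma2)

    likelihood = np.exp(-dev2 / (2.0 * sigma2[None, :])).mean(axis=0)
    prior = membership.mean(axis=0)
    post = likelihood * prior
    total = post.sum()
    if total == 0.0:  # all likelihoods underflowed: fall back to the prior
        post = prior.copy()
        total = post.sum()
    posterior = post / total
    return VQModel(
        codebook=codebook,
        rho_abs=rho_abs,
        membership=membership,
        mu=mu,
        sigma2=sigma2,
        prior=prior,
        likelihood=likelihood,
        posterior=posterior,
    )


def vq_model(
    window: np.ndarray,
    params: EntropyParams,
    rho_abs: float | None = None,
    squared_tolerance: bool = False,
) -> VQModel:
    """Full pipeline on a window: embed, build codebook, fit the model.

    The tolerance is ``params.rho`` times the window's standard deviation
    unless an absolute ``rho_abs`` (signal units) is supplied, as
    sliding-window analyses do to keep it fixed across windows.
    """
    window = np.asarray(window, dtype=float).ravel()
    if window.size < params.M + 2:
        raise ValueError(
            f"window length {window.size} must be >= M+2 = {params.M + 2}"
        )
    if rho_abs is None:
        rho_abs = params.rho * float(np.std(window))
    if rho_abs == 0.0:
        raise ValueError("zero tolerance has no scale; handled by vq_entropy")
    emb = embed(window, params.M)
    codebook = build_codebook(emb, rho_abs, squared_tolerance)
    return fit_vq_model(emb, codebook, rho_abs)


def vq_entropy(
    window: np.ndarray,
    params: EntropyParams,
    rho_abs: float | None = None,
    squared_tolerance: bool = False,
) -> float:
    """VQEnt (nats): Shannon entropy of the posterior over VQ codes.

    Bounded by ``0 <= H <= ln Q'``. A constant window quantizes to a
    single code and returns 0. Tolerance semantics are as in
    :func:`vq_model`.
    """
    window = np.asarray(window, dtype=float).ravel()
    if window.size < params.M + 2:
        raise ValueError(
            f"window length {window.size} must be >= M+2 = {params.M + 2}"
        )
    if rho_abs == 0.0 or (rho_abs is None and float(np.std(window)) == 0.0):
        return 0.0
    return vq_model(window, params, rho_abs, squared_tolerance).entropy()
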