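"""ERD/S time-courses: classical power ratio and sliding-window entropy.

Event-related desynchronization/synchronization (ERD/S) is the relative
change of a band-limited EEG quantity against a pre-stimulus reference.
The classical estimate is the trial-averaged instantaneous power
normalized to the reference interval,

    zeta(t) = (xi(t) - xi_ref) / xi_ref,

a dimensionless ratio (-1 = total suppression). The entropy variant
replaces trial-averaged power by a per-trial entropy trajectory computed
on sliding windows (length tau, typically 90% overlap), which needs no
reference power and remains defined for a single trial; the trial average
is taken afterwards and the per-trial courses are retained for
classification. Courses are indexed by window-center times so power and
entropy courses share one time axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import TrialSet
from .embedding_entropy import EntropyParams, fuzzy_entropy, sample_entropy
from .vq_entropy import vq_entropy

logger = logging.getLogger(__name__)

__all__ = ["WindowPlan", "ErdsCourse", "plan_windows", "power_erds", "entropy_erds"]

_ESTIMATOR_FUNCS = {
    "sampen": sample_entropy,
    "fuzzyen": fuzzy_entropy,
    "vqent": vq_entropy,
}


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout over an analyzed segment."""

    tau: float
    overlap: float
    n_tau: int
    starts: np.ndarray  # sample indices
    centers: np.ndarray  # seconds

    @property
    def n_windows(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class ErdsCourse:
    """A per-channel ERD/S trajectory (power ratio or entropy in nats)."""

    values: np.ndarray  # channels x windows (trial-averaged)
    time_axis: np.ndarray  # seconds (window centers / sample times)
    channel_names: tuple[str, ...]
    mode: str  # {power, entropy}
    estimator: str = "power"
    per_trial: np.ndarray | None = None  # N x channels x windows

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "time_axis", np.asarray(self.time_axis, dtype=float))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.values.shape != (len(self.channel_names), len(self.time_axis)):
            raise ValueError("values must be channels x time points")

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channel_names.index(name)]


def plan_windows(
    segment_length: float, tau: float, overlap: float, rate: float
) -> WindowPlan:
    """Plan sliding windows of length ``tau`` seconds with fractional
    ``overlap`` over a segment; windows lie fully inside the segment."""
    if tau <= 0 or not (0 <= overlap < 1):
        raise ValueError("need tau > 0 and 0 <= overlap < 1")
    if tau > segment_length + 1e-9:
        raise ValueError(f"tau={tau} exceeds segment length {segment_length}")
    n_tau = int(round(tau * rate))
    n_seg = int(round(segment_length * rate))
    step = int(round(n_tau * (1.0 - overlap)))
    if step < 1:
        raise ValueError("window step underflows one sample; reduce overlap")
    starts = np.arange(0, n_seg - n_tau + 1, step)
    centers = (starts + n_tau / 2.0) / rate
    return WindowPlan(tau=tau, overlap=overlap, n_tau=n_tau, starts=starts, centers=centers)


def power_erds(
    trials: TrialSet,
    smooth: float | None = None,
    variance_ratio_warn: float = 10.0,
) -> ErdsCourse:
    """Classical power ERD/S per channel at full sample resolution.

    The instantaneous power is squared amplitude averaged across trials;
    the reference level is its mean over the trial set's reference window.
    ``smooth`` optionally applies a moving average of that many seconds
    for display. A diagnostic warns when the power scatter over time is
    not much larger than the scatter of the reference level
    (``var(xi_t)/var(xi_ref-samples)`` below ``variance_ratio_warn``),
    which signals an unstable baseline.
    """
    xi = np.mean(trials.trials**2, axis=0)  # channels x samples
    r0, r1 = trials.reference_window
    i0 = int(round(r0 * trials.rate))
    i1 = int(round(r1 * trials.rate))
    if i1 <= i0:
        raise ValueError("degenerate reference window")
    ref = xi[:, i0:i1]
    xi_bar = ref.mean(axis=1)
    if np.any(xi_bar == 0.0):
        raise ValueError("zero reference power on some channel")
    zeta = (xi - xi_bar[:, None]) / xi_bar[:, None]

    var_t = xi.var(axis=1)
    var_ref = ref.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(var_ref > 0, var_t / var_ref, np.inf)
    bad = ratio < variance_ratio_warn
    if np.any(bad):
        logger.warning(
            "power_erds: var(xi_t) not >> var(xi_ref) on %d channel(s) "
            "(min ratio %.2f); baseline may be unstable",
            int(bad.sum()),
            float(ratio.min()),
        )

    if smooth is not None and smooth > 0:
        k = max(1, int(round(smooth * trials.rate)))
        kernel = np.ones(k) / k
        zeta = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), -1, zeta
        )
    t = np.arange(trials.n_samples) * trials.sample_interval
    return ErdsCourse(
        values=zeta,
        time_axis=t,
        channel_names=trials.channel_names,
        mode="power",
        estimator="power",
    )


def entropy_erds(
    trials: TrialSet,
    plan: WindowPlan,
    params: EntropyParams,
    channels: Sequence[str] | None = None,
    tolerance_scope: str = "trial",
) -> ErdsCourse:
    """Sliding-window entropy trajectory per trial and channel.

    Returns the trial-averaged course; single-trial courses are kept in
    ``per_trial``. Windows where the estimator is undefined (sample
    entropy with zero matches) yield NaN in ``per_trial`` and are
    excluded from the trial average, with a logged count.

    With ``tolerance_scope='trial'`` (default) the absolute tolerance is
    ``params.rho`` times the standard deviation of the whole trial on
    that channel, held fixed across the sliding windows; an amplitude
    drop during the MI interval then lowers the entropy estimate instead
    of being normalized away. ``'window'`` rescales per window.
    """
    if tolerance_scope not in ("trial", "window"):
        raise ValueError("tolerance_scope must be 'trial' or 'window'")
    func = _ESTIMATOR_FUNCS[params.estimator]
    if channels is None:
        ch_idx = list(range(trials.n_channels))
        ch_names = trials.channel_names
    else:
        ch_idx = [trials.channel_index(c) for c in channels]
        ch_names = tuple(channels)
    n, w = trials.n_trials, plan.n_windows
    per_trial = np.empty((n, len(ch_idx), w))
    data = trials.trials
    for ci, c in enumerate(ch_idx):
        if tolerance_scope == "trial":
            tols = params.rho * data[:, c, :].std(axis=-1)
        for wi, s in enumerate(plan.starts):
            seg = data[:, c, s : s + plan.n_tau]
            for ti in range(n):
                tol = tols[ti] if tolerance_scope == "trial" else None
                per_trial[ti, ci, wi] = func(seg[ti], params, rho_abs=tol)
    n_nan = int(np.isnan(per_trial).sum())
    if n_nan:
        logger.info("entropy_erds: %d NaN window(s) excluded from the average", n_nan)
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(per_trial, axis=0)
    return ErdsCourse(
        values=avg,
        time_axis=plan.centers.copy(),
        channel_names=ch_names,
        mode="entropy",
        estimator=params.estimator,
        per_trial=per_trial,
    )
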