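"""Synthetic two-class motor-imagery EEG with known ERD ground truth.

Each trial is spectrally shaped 1/f^a background noise on every channel,
plus a mu-band oscillation (random phase, +-20% amplitude jitter across
trials) on the two sensorimotor channels. On the channel contralateral
to the imagined hand the mu amplitude is multiplied by ``1 - erd_depth``
inside the ERD interval, with 0.25 s raised-cosine on/off ramps to avoid
spectral splatter at the boundaries. Channels can then be mixed by a
row-normalized distance-kernel matrix emulating volume conduction.

Together with a tolerance that is fixed from the whole trial (see
:mod:`vqent.erds`), the mu suppression reproduces the empirical MI
signature that both band power and windowed entropy drop on the
contralateral channel during imagery: inside the ERD interval the signal
excursions shrink relative to the fixed tolerance, patterns match more
easily, and all three estimators fall together with power.

Volume conduction (``mixing_strength`` > 0) has two effects, both scaled
by the same parameter: channels are linearly mixed by a row-normalized
distance-kernel matrix, and a spatially smooth mu-band oscillation from
a distant (posterior) source, unmodulated by the task, is superimposed
on all channels. The second is what masks the ERD on the raw sensors —
it occupies the same band as the local mu rhythm — and is what a surface
Laplacian removes, since a smooth field is nearly constant across a
channel and its neighbors.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .core_io import IV2A_CHANNELS, Montage, TrialSet, default_montage

__all__ = ["SynthSpec", "generate", "ground_truth", "montage_for", "mixing_matrix"]

RAMP_S = 0.25  # raised-cosine ERD on/off ramp length


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration; defaults emulate a cue-paced two-class
    22-channel MI recording at 250 Hz with a 60% contralateral mu ERD."""

    n_trials_per_class: int = 50
    n_channels: int = 22
    rate: float = 250.0
    trial_duration: float = 7.0
    mu_band: tuple[float, float] = (8.0, 13.0)
    erd_depth: float = 0.6
    erd_interval: tuple[float, float] = (2.5, 4.5)
    contralateral_map: Mapping[str, str] = field(
        default_factory=lambda: {"right": "C3", "left": "C4"}
    )
    noise_exponent: float = 1.0
    snr: float = 2.0
    mixing_strength: float = 0.0
    amplitude_jitter: float = 0.2
    reference_window: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must be in [0, 1]")
        t0, t1 = self.erd_interval
        if not (0 <= t0 < t1 <= self.trial_duration):
            raise ValueError("erd_interval must lie inside the trial")
        if self.n_channels < 2:
            raise ValueError("need at least the two sensorimotor channels")
        if not (0.0 <= self.mixing_strength < 1.0):
            raise ValueError("mixing_strength must be in [0, 1)")
        if self.snr < 0 or self.rate <= 0 or self.n_trials_per_class < 1:
            raise ValueError("invalid spec")
        names = self.channel_names
        for ch in self.contralateral_map.values():
            if ch not in names:
                raise ValueError(f"contralateral channel {ch!r} not in layout")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return _layout(self.n_channels)[0]

    @property
    def mu_freq(self) -> float:
        return 0.5 * (self.mu_band[0] + self.mu_band[1])


def _layout(n_channels: int) -> tuple[tuple[str, ...], dict[str, tuple[float, float]]]:
    """Channel names and scalp positions. 22 channels use the standard
    benchmark layout; otherwise C3/C4 analogues over the hand areas plus
    filler channels on a surrounding ring."""
    if n_channels == 22:
        return IV2A_CHANNELS, {}
    names = ["C3", "C4"] + [f"ch{i}" for i in range(3, n_channels + 1)]
    pos: dict[str, tuple[float, float]] = {"C3": (-0.45, 0.0), "C4": (0.45, 0.0)}
    n_extra = n_channels - 2
    for i in range(n_extra):
        ang = 2.0 * np.pi * i / n_extra
        pos[names[2 + i]] = (0.8 * np.cos(ang), 0.8 * np.sin(ang))
    return tuple(names), pos


def montage_for(spec: SynthSpec) -> Montage:
    names, pos = _layout(spec.n_channels)
    return default_montage(names, positions=pos or None)


def mixing_matrix(spec: SynthSpec) -> np.ndarray:
    """Row-normalized volume-conduction matrix from scalp distances.

    ``(1 - s) I + s K`` with K a broad Gaussian distance kernel
    (bandwidth 0.4 head radii) over the other channels; rows sum to 1.
    """
    mont = montage_for(spec)
    pos = mont.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2 * 0.4**2))
    np.fill_diagonal(k, 0.0)
    k /= k.sum(axis=1, keepdims=True)
    n = spec.n_channels
    return (1.0 - spec.mixing_strength) * np.eye(n) + spec.mixing_strength * k


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                rate: float, exponent: float) -> np.ndarray:
    """1/f^a noise by spectral shaping of white noise, unit std per series."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape_f = np.ones_like(freqs)
    nz = freqs > 0
    shape_f[nz] = freqs[nz] ** (-exponent / 2.0)
    shape_f[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape_f, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _erd_envelope(spec: SynthSpec, t: np.ndarray) -> np.ndarray:
    """Mu-amplitude envelope on the contralateral channel: 1 outside the
    ERD interval, ``1 - erd_depth`` inside, raised-cosine ramps."""
    t0, t1 = spec.erd_interval
    ramp = min(RAMP_S, (t1 - t0) / 2.0)
    env = np.ones_like(t)
    depth = spec.erd_depth
    inside = (t >= t0 + ramp) & (t < t1 - ramp)
    env[inside] = 1.0 - depth
    down = (t >= t0) & (t < t0 + ramp)
    frac = (t[down] - t0) / ramp
    env[down] = 1.0 - depth * 0.5 * (1.0 - np.cos(np.pi * frac))
    up = (t >= t1 - ramp) & (t < t1)
    frac = (t[up] - (t1 - ramp)) / ramp
    env[up] = 1.0 - depth * 0.5 * (1.0 + np.cos(np.pi * frac))
    return env


def generate(spec: SynthSpec) -> TrialSet:
    """Generate the labeled synthetic trial set described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    names = spec.channel_names
    n_samp = int(round(spec.trial_duration * spec.rate))
    n_total = 2 * spec.n_trials_per_class
    t = np.arange(n_samp) / spec.rate

    labels = np.array(
        ["left"] * spec.n_trials_per_class + ["right"] * spec.n_trials_per_class
    )
    rng.shuffle(labels)

    data = _pink_noise(
        rng, (n_total, spec.n_channels), n_samp, spec.rate, spec.noise_exponent
    )

    env = _erd_envelope(spec, t)
    sm_channels = sorted(set(spec.contralateral_map.values()))
    sm_idx = {ch: names.index(ch) for ch in sm_channels}
    for n in range(n_total):
        contra = spec.contralateral_map[labels[n]]
        for ch, ci in sm_idx.items():
            phase = rng.uniform(0.0, 2.0 * np.pi)
            jitter = 1.0 + spec.amplitude_jitter * rng.uniform(-1.0, 1.0)
            amp = spec.snr * jitter
            mu = amp * np.sin(2.0 * np.pi * spec.mu_freq * t + phase)
            if ch == contra:
                mu = mu * env
            data[n, ci, :] += mu

    if spec.mixing_strength > 0.0:
        # distant idle rhythm: same band, no task modulation, smooth
        # spatial profile peaking posteriorly
        pos = montage_for(spec).positions
        src = np.array([0.0, -0.6])
        gain = np.exp(-((pos - src) ** 2).sum(-1) / (2 * 1.2**2))
        amp_g = spec.mixing_strength * spec.snr * 1.5
        for n in range(n_total):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            jitter = 1.0 + spec.amplitude_jitter * rng.uniform(-1.0, 1.0)
            alpha = amp_g * jitter * np.sin(2.0 * np.pi * spec.mu_freq * t + phase)
            data[n] += gain[:, None] * alpha[None, :]
        mix = mixing_matrix(spec)
        data = np.einsum("ij,njs->nis", mix, data)

    return TrialSet(
        trials=data,
        labels=tuple(labels),
        sample_interval=1.0 / spec.rate,
        channel_names=names,
        mi_window=spec.erd_interval,
        reference_window=spec.reference_window,
    )


def ground_truth(spec: SynthSpec) -> list[dict]:
    """Machine-readable description of the programmed effects.

    One record per class with a non-zero effect: affected channel, ERD
    interval, plateau (interval minus ramps, where the full depth holds),
    amplitude depth and the implied plateau power ratio
    ``(1 - depth)^2 - 1``. JSON-serializable.
    """
    if spec.erd_depth == 0.0:
        return []
    t0, t1 = spec.erd_interval
    ramp = min(RAMP_S, (t1 - t0) / 2.0)
    effects = []
    for cls, ch in sorted(spec.contralateral_map.items()):
        effects.append(
            {
                "class": cls,
                "channel": ch,
                "interval": [t0, t1],
                "plateau": [t0 + ramp, t1 - ramp],
                "depth": spec.erd_depth,
                "power_ratio": (1.0 - spec.erd_depth) ** 2 - 1.0,
            }
        )
    return effects


def spec_to_dict(spec: SynthSpec) -> dict:
    d = asdict(spec)
    d["contralateral_map"] = dict(spec.contralateral_map)
    return d
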