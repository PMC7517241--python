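"""Data containers and I/O for epoched motor-imagery EEG.

The canonical on-disk interchange format is ``.npz`` (arrays plus
JSON-encoded metadata). EDF/GDF reading is available when ``mne`` is
installed; it is an optional dependency and its absence produces a clear
error rather than an import failure.

Time coordinates are seconds from trial start (trial start = 0) and all
intervals are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "TrialSet",
    "Montage",
    "EventSchema",
    "read_trials",
    "write_trials",
    "write_course",
    "read_course",
    "epoch_recording",
    "default_montage",
    "IV2A_CHANNELS",
    "SENSORIMOTOR_GROUPS",
]

# 22-channel layout used by the standard four-class motor-imagery benchmark
# montage. Channels are addressed by their montage number, except C3 (8) and
# C4 (12) which carry their 10-20 names so sensorimotor groups are
# addressable the way the literature refers to them.
IV2A_CHANNELS: tuple[str, ...] = (
    "1", "2", "3", "4", "5", "6",
    "7", "C3", "9", "10", "11", "C4", "13",
    "14", "15", "16", "17", "18",
    "19", "20", "21", "22",
)

# Approximate 2-D scalp positions (unit head disc, nose up) for the rows
# Fz / FC / C / CP / P / POz of the 22-channel layout.
_IV2A_POSITIONS: dict[str, tuple[float, float]] = {
    "1": (0.0, 0.67),
    "2": (-0.45, 0.33), "3": (-0.22, 0.33), "4": (0.0, 0.33),
    "5": (0.22, 0.33), "6": (0.45, 0.33),
    "7": (-0.67, 0.0), "C3": (-0.45, 0.0), "9": (-0.22, 0.0),
    "10": (0.0, 0.0), "11": (0.22, 0.0), "C4": (0.45, 0.0),
    "13": (0.67, 0.0),
    "14": (-0.45, -0.33), "15": (-0.22, -0.33), "16": (0.0, -0.33),
    "17": (0.22, -0.33), "18": (0.45, -0.33),
    "19": (-0.22, -0.67), "20": (0.0, -0.67), "21": (0.22, -0.67),
    "22": (0.0, -0.9),
}

SENSORIMOTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "left": ("C3", "9", "14", "15"),
    "right": ("C4", "11", "18", "17"),
    "midline": ("10", "16"),
}


@dataclass(frozen=True)
class Recording:
    """A continuous multichannel recording (channels x samples, microvolts)."""

    data: np.ndarray
    sample_interval: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError("data must be channels x samples with >=2 samples")
        if len(self.channel_names) != data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def rate(self) -> float:
        return 1.0 / self.sample_interval

    @property
    def total_duration(self) -> float:
        return self.data.shape[1] * self.sample_interval


@dataclass(frozen=True)
class EventSchema:
    """Trial timing: where the cue falls and how long a trial lasts.

    ``label_map`` translates integer event codes to class labels; events
    with codes outside the map are dropped (with a logged count).
    """

    trial_duration: float = 7.0
    cue_time: float = 2.0
    mi_window: tuple[float, float] = (2.5, 4.5)
    reference_window: tuple[float, float] = (0.5, 1.5)
    label_map: Mapping[int, str] = field(
        default_factory=lambda: {769: "left", 770: "right"}
    )


@dataclass(frozen=True)
class TrialSet:
    """Labeled epoched EEG trials: ``trials`` is N x channels x samples."""

    trials: np.ndarray
    labels: tuple[str, ...]
    sample_interval: float
    channel_names: tuple[str, ...]
    mi_window: tuple[float, float] = (2.5, 4.5)
    reference_window: tuple[float, float] = (0.5, 1.5)
    cue_time: float = 2.0

    def __post_init__(self) -> None:
        trials = np.asarray(self.trials, dtype=float)
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "mi_window", tuple(self.mi_window))
        object.__setattr__(self, "reference_window", tuple(self.reference_window))
        if trials.ndim != 3:
            raise ValueError("trials must be N x channels x samples")
        if len(self.labels) != trials.shape[0]:
            raise ValueError("one label per trial required")
        if len(self.channel_names) != trials.shape[1]:
            raise ValueError("channel_names must match channel axis")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        dur = self.duration
        for name, (t0, t1) in (
            ("mi_window", self.mi_window),
            ("reference_window", self.reference_window),
        ):
            if not (0 <= t0 < t1 <= dur + 1e-9):
                raise ValueError(f"{name} {t0, t1} not inside [0, {dur}]")
        if self.reference_window[0] > self.mi_window[0]:
            raise ValueError("reference_window must precede mi_window")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def rate(self) -> float:
        return 1.0 / self.sample_interval

    @property
    def duration(self) -> float:
        return self.n_samples * self.sample_interval

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def select_channels(self, names: Sequence[str]) -> "TrialSet":
        idx = [self.channel_index(n) for n in names]
        return replace(
            self, trials=self.trials[:, idx, :], channel_names=tuple(names)
        )

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)


@dataclass(frozen=True)
class Montage:
    """Per-channel 2-D positions and a symmetric neighbor structure."""

    channel_names: tuple[str, ...]
    positions: np.ndarray
    neighbors: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(
            self, "neighbors", tuple(tuple(n) for n in self.neighbors)
        )
        n = len(self.channel_names)
        if pos.shape != (n, 2):
            raise ValueError("positions must be n_channels x 2")
        if len(self.neighbors) != n:
            raise ValueError("one neighbor list per channel required")
        for i, nbrs in enumerate(self.neighbors):
            if i in nbrs:
                raise ValueError("self-neighbors are not allowed")
            for j in nbrs:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    def group(self, name: str) -> tuple[str, ...]:
        """Sensorimotor channel group (``left``/``right``/``midline``)."""
        try:
            members = SENSORIMOTOR_GROUPS[name]
        except KeyError:
            raise KeyError(f"unknown group {name!r}") from None
        missing = [m for m in members if m not in self.channel_names]
        if missing:
            raise KeyError(f"group {name!r} channels missing: {missing}")
        return members

    def adjacency_matrix(self) -> np.ndarray:
        n = len(self.channel_names)
        adj = np.zeros((n, n), dtype=bool)
        for i, nbrs in enumerate(self.neighbors):
            adj[i, list(nbrs)] = True
        return adj


def default_montage(
    channel_names: Sequence[str],
    positions: Mapping[str, tuple[float, float]] | None = None,
    n_neighbors: int = 4,
) -> Montage:
    """Build a montage with symmetrized k-nearest-neighbor adjacency.

    Channel names from the 22-channel layout resolve to built-in scalp
    positions; any other name must appear in ``positions``.
    """
    channel_names = tuple(channel_names)
    coords = []
    for name in channel_names:
        if positions is not None and name in positions:
            coords.append(positions[name])
        elif name in _IV2A_POSITIONS:
            coords.append(_IV2A_POSITIONS[name])
        else:
            raise KeyError(f"no position known for channel {name!r}")
    pos = np.asarray(coords, dtype=float)
    n = len(channel_names)
    k = min(n_neighbors, n - 1)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    if k > 0:
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(n):
            order = np.argsort(d2[i], kind="stable")[:k]
            for j in order:
                neighbors[i].add(int(j))
                neighbors[int(j)].add(i)  # symmetrize by union
    return Montage(
        channel_names=channel_names,
        positions=pos,
        neighbors=tuple(tuple(sorted(s)) for s in neighbors),
    )


def epoch_recording(
    recording: Recording,
    event_onsets: Sequence[float],
    event_labels: Sequence[str],
    schema: EventSchema,
) -> TrialSet:
    """Cut fixed-length trials out of a continuous recording.

    ``event_onsets`` are trial-start times in seconds. Trials that would
    read outside the recording are dropped with a logged count.
    """
    if len(event_onsets) != len(event_labels):
        raise ValueError("one label per event onset required")
    n_samp = int(round(schema.trial_duration / recording.sample_interval))
    total = recording.data.shape[1]
    trials, labels, dropped = [], [], 0
    for t0, lab in zip(event_onsets, event_labels):
        i0 = int(round(t0 / recording.sample_interval))
        if i0 < 0 or i0 + n_samp > total:
            dropped += 1
            continue
        trials.append(recording.data[:, i0 : i0 + n_samp])
        labels.append(lab)
    if dropped:
        logger.info("epoch_recording: dropped %d out-of-bounds trials", dropped)
    if not trials:
        raise ValueError("no labeled events produced a full trial")
    return TrialSet(
        trials=np.stack(trials),
        labels=tuple(labels),
        sample_interval=recording.sample_interval,
        channel_names=recording.channel_names,
        mi_window=schema.mi_window,
        reference_window=schema.reference_window,
        cue_time=schema.cue_time,
    )


def write_trials(trials: TrialSet, path: str | Path) -> None:
    """Serialize a :class:`TrialSet` to npz (lossless round-trip)."""
    meta = {
        "labels": list(trials.labels),
        "channel_names": list(trials.channel_names),
        "sample_interval": trials.sample_interval,
        "mi_window": list(trials.mi_window),
        "reference_window": list(trials.reference_window),
        "cue_time": trials.cue_time,
    }
    np.savez(Path(path), trials=trials.trials, meta=json.dumps(meta))


def _read_trials_npz(path: Path) -> TrialSet:
    with np.load(path, allow_pickle=False) as f:
        arr = f["trials"]
        meta = json.loads(str(f["meta"]))
    return TrialSet(
        trials=arr,
        labels=tuple(meta["labels"]),
        sample_interval=float(meta["sample_interval"]),
        channel_names=tuple(meta["channel_names"]),
        mi_window=tuple(meta["mi_window"]),
        reference_window=tuple(meta["reference_window"]),
        cue_time=float(meta.get("cue_time", 2.0)),
    )


def _read_trials_mne(path: Path, fmt: str, schema: EventSchema) -> TrialSet:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            f"reading {fmt} files requires the optional dependency 'mne' "
            "(pip install vqent[mne])"
        ) from exc
    reader = mne.io.read_raw_gdf if fmt == "gdf" else mne.io.read_raw_edf
    raw = reader(str(path), preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code_of = {v: k for k, v in event_id.items()}
    onsets, labels = [], []
    dropped = 0
    for samp, _, code in events:
        try:
            raw_code = int(code_of[code])
        except (ValueError, KeyError):
            dropped += 1
            continue
        if raw_code not in schema.label_map:
            dropped += 1
            continue
        # event marks the cue; trial starts cue_time earlier
        onsets.append(samp / raw.info["sfreq"] - schema.cue_time)
        labels.append(schema.label_map[raw_code])
    logger.info("read_trials: %d unlabeled/unknown events skipped", dropped)
    if not labels:
        raise ValueError(f"no labeled events found in {path}")
    rec = Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        sample_interval=1.0 / raw.info["sfreq"],
        channel_names=tuple(raw.ch_names),
    )
    return epoch_recording(rec, onsets, labels, schema)


def read_trials(
    path: str | Path,
    format: str | None = None,
    event_schema: EventSchema | None = None,
) -> TrialSet:
    """Read a :class:`TrialSet` from npz (canonical) or EDF/GDF.

    The format is inferred from the suffix when not given. EDF/GDF files
    are epoched with ``event_schema`` (defaults describe a 7 s cue-paced
    trial with the cue at 2 s).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "npz":
        return _read_trials_npz(path)
    if fmt in ("edf", "gdf"):
        return _read_trials_mne(path, fmt, event_schema or EventSchema())
    raise ValueError(f"unsupported trial format {fmt!r}")


def write_course(course, path: str | Path, format: str | None = None) -> None:
    """Write an ERD/S time-course to CSV (long form) or npz (lossless)."""
    from .erds import ErdsCourse  # local import to avoid a cycle

    if not isinstance(course, ErdsCourse):
        raise TypeError("course must be an ErdsCourse")
    if course.values.size == 0:
        raise ValueError("refusing to write an empty course")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        import pandas as pd

        rows = pd.DataFrame(
            {
                "channel": np.repeat(course.channel_names, len(course.time_axis)),
                "window_center_s": np.tile(course.time_axis, len(course.channel_names)),
                "value": course.values.ravel(),
            }
        )
        rows.to_csv(path, index=False)
    elif fmt == "npz":
        meta = {
            "channel_names": list(course.channel_names),
            "mode": course.mode,
            "estimator": course.estimator,
        }
        payload = {
            "values": course.values,
            "time_axis": course.time_axis,
            "meta": json.dumps(meta),
        }
        if course.per_trial is not None:
            payload["per_trial"] = course.per_trial
        np.savez(path, **payload)
    else:
        raise ValueError(f"unsupported course format {fmt!r}")


def read_course(path: str | Path):
    """Read an npz-serialized :class:`~vqent.erds.ErdsCourse`."""
    from .erds import ErdsCourse

    with np.load(Path(path), allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        return ErdsCourse(
            values=f["values"],
            time_axis=f["time_axis"],
            channel_names=tuple(meta["channel_names"]),
            mode=meta["mode"],
            estimator=meta["estimator"],
            per_trial=f["per_trial"] if "per_trial" in f else None,
        )
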