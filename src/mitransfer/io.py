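"""Trial/recording data model and file I/O.

The exchange objects used throughout the package:

* :class:`RawRecording` — a continuous multichannel EEG recording in
  microvolts, with cue/event markers.
* :class:`TrialTensor` — an epoched ``(M, C, T)`` tensor of trials with
  integer class labels.
* :class:`SplitSpec` — a reproducible stratified train/test partition.

EDF (European Data Format) is supported as the on-disk interchange format:
reading goes through :func:`mne.io.read_raw_edf`; writing uses a minimal
built-in EDF+C writer (16-bit, one data record, a TAL annotation channel
for event markers).  The internal trial archive is a NumPy ``.npz``
container holding the float32 tensor plus labels and metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np


class EDFFormatError(ValueError):
    """Raised when an EDF file cannot be parsed or written."""


@dataclass
class RawRecording:
    """Continuous recording: ``signal`` is (C channels x S samples), microvolts."""

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    event_markers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError(f"signal must be 2-D (C, S), got shape {self.signal.shape}")
        c, s = self.signal.shape
        if c <= 0 or s <= 0:
            raise ValueError("signal must have at least one channel and one sample")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if len(set(self.channel_names)) != c:
            raise ValueError("channel names must be distinct")
        for idx, (sample, _code) in enumerate(self.event_markers):
            if not 0 <= sample < s:
                raise ValueError(
                    f"event {idx} at sample {sample} outside recording [0, {s})"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialTensor:
    """Epoched trials: ``data`` is (M trials x C channels x T samples)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    class_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (M, C, T), got shape {self.data.shape}")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match M={self.data.shape[0]}"
            )
        n = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= n):
            raise ValueError(f"labels must lie in [0, {n})")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices: Sequence[int]) -> "TrialTensor":
        idx = np.asarray(indices, dtype=np.int64)
        return TrialTensor(
            data=self.data[idx], labels=self.labels[idx], fs=self.fs,
            class_names=list(self.class_names),
        )


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test indices over ``[0, M)``, reproducible from ``seed``."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        train = np.asarray(self.train_indices, dtype=np.int64)
        test = np.asarray(self.test_indices, dtype=np.int64)
        object.__setattr__(self, "train_indices", train)
        object.__setattr__(self, "test_indices", test)
        if np.intersect1d(train, test).size:
            raise ValueError("train and test indices overlap")


# ---------------------------------------------------------------------------
# EDF writing (minimal EDF+C) and reading (via MNE)
# ---------------------------------------------------------------------------

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


def _edf_field(value: str, width: int) -> bytes:
    raw = value.encode("ascii")
    if len(raw) > width:
        raise EDFFormatError(f"EDF header field {value!r} exceeds {width} bytes")
    return raw.ljust(width)


def _edf_number(value: float, width: int) -> bytes:
    """Format a number into a fixed-width ASCII EDF field, maximising precision."""
    if value == int(value) and abs(value) < 10 ** width:
        text = str(int(value))
        if len(text) <= width:
            return _edf_field(text, width)
    for dec in range(width - 2, -1, -1):
        text = f"{value:.{dec}f}"
        if len(text) <= width:
            return _edf_field(text, width)
    raise EDFFormatError(f"cannot format {value} into {width} ASCII bytes")


def write_edf(rec: RawRecording, path: str | os.PathLike) -> None:
    """Write a recording as EDF+C with event markers in a TAL annotation channel.

    The whole signal is stored as a single data record of duration ``S / fs``
    (which must be representable in the 8-byte ASCII duration field; integer
    sample rates and second-aligned durations always are).  Amplitudes are
    quantized to 16 bits over a symmetric per-channel physical range.
    """
    c, s = rec.signal.shape
    duration = s / rec.fs

    # One TAL per event: "+onset\x14code\x14\x00", preceded by the record
    # timestamp TAL "+0\x14\x14\x00".
    tal = b"+0\x14\x14\x00"
    for sample, code in rec.event_markers:
        onset = sample / rec.fs
        tal += f"+{onset:.7f}\x14{code}\x14\x00".encode("utf-8")
    n_annot_samples = (len(tal) + 1) // 2 + 16  # int16 samples; headroom
    tal = tal.ljust(2 * n_annot_samples, b"\x00")

    n_signals = c + 1
    header_bytes = 256 * (1 + n_signals)

    amp = np.max(np.abs(rec.signal), axis=1)
    amp = np.where(amp > 0, amp, 1.0)
    phys_min = -amp
    phys_max = amp

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))
        fh.write(_edf_field("Startdate X X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("EDF+C", 44))
        fh.write(_edf_field("1", 8))  # one data record
        fh.write(_edf_number(duration, 8))
        fh.write(_edf_field(str(n_signals), 4))

        labels = list(rec.channel_names) + ["EDF Annotations"]
        fh.write(b"".join(_edf_field(lbl, 16) for lbl in labels))
        fh.write(b"".join(_edf_field("", 80) for _ in labels))
        fh.write(b"".join(_edf_field("uV", 8) for _ in range(c)) + _edf_field("", 8))
        fh.write(
            b"".join(_edf_number(v, 8) for v in phys_min) + _edf_number(-1, 8)
        )
        fh.write(
            b"".join(_edf_number(v, 8) for v in phys_max) + _edf_number(1, 8)
        )
        fh.write(b"".join(_edf_field(str(_EDF_DIG_MIN), 8) for _ in labels))
        fh.write(b"".join(_edf_field(str(_EDF_DIG_MAX), 8) for _ in labels))
        fh.write(b"".join(_edf_field("", 80) for _ in labels))
        spr = [str(s)] * c + [str(n_annot_samples)]
        fh.write(b"".join(_edf_field(v, 8) for v in spr))
        fh.write(b"".join(_edf_field("", 32) for _ in labels))

        scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
        digital = np.rint(
            (rec.signal - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN
        )
        digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
        fh.write(digital.tobytes())
        fh.write(tal)


def read_edf(path: str | os.PathLike) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (microvolts).

    Annotations are mapped to ``event_markers`` as
    ``(round(onset * fs), description)`` pairs.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # corrupt/truncated headers surface as ValueError etc.
        raise EDFFormatError(f"cannot parse EDF file {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # MNE holds EEG in volts; model uses microvolts
    events: list[tuple[int, str]] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        sample = int(round(float(onset) * fs))
        if 0 <= sample < data.shape[1]:
            events.append((sample, str(desc)))
    return RawRecording(
        signal=data, fs=fs, channel_names=list(raw.ch_names), event_markers=events
    )


# ---------------------------------------------------------------------------
# Internal trial archive (.npz)
# ---------------------------------------------------------------------------

def save_trials(trials: TrialTensor, path: str | os.PathLike) -> None:
    """Save a trial tensor to the internal ``.npz`` archive (float32 data)."""
    np.savez(
        path,
        data=trials.data.astype("<f4"),
        labels=trials.labels.astype("<i8"),
        fs=np.float64(trials.fs),
        class_names=np.asarray(trials.class_names, dtype="U"),
    )


def load_trials(path: str | os.PathLike) -> TrialTensor:
    with np.load(path, allow_pickle=False) as archive:
        return TrialTensor(
            data=archive["data"].astype(np.float64),
            labels=archive["labels"],
            fs=float(archive["fs"]),
            class_names=[str(n) for n in archive["class_names"]],
        )


def export_labels(trials: TrialTensor, path: str | os.PathLike) -> None:
    """Export labels as delimited text: ``trial_index<TAB>class_name``."""
    with open(path, "w") as fh:
        fh.write("trial_index\tclass_name\n")
        for i, lab in enumerate(trials.labels):
            fh.write(f"{i}\t{trials.class_names[int(lab)]}\n")


# ---------------------------------------------------------------------------
# Epoching and splitting
# ---------------------------------------------------------------------------

def epoch_trials(
    rec: RawRecording,
    label_map: Mapping[str, int],
    epoch_start_offset_s: float = 0.0,
    epoch_len_s: float = 3.0,
    class_names: Sequence[str] | None = None,
) -> TrialTensor:
    """Cut labelled cue-aligned epochs out of a continuous recording.

    Every event whose code appears in ``label_map`` yields one trial of
    ``round(epoch_len_s * fs)`` samples starting ``epoch_start_offset_s``
    after the cue.  Samples are copied verbatim (no filtering).
    """
    t_len = int(round(epoch_len_s * rec.fs))
    if t_len <= 0:
        raise ValueError("epoch length must span at least one sample")
    offset = int(round(epoch_start_offset_s * rec.fs))
    segments, labels = [], []
    for trial_idx, (sample, code) in enumerate(rec.event_markers):
        if code not in label_map:
            continue
        start = sample + offset
        stop = start + t_len
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"trial {trial_idx} (cue at sample {sample}) epoch [{start}, {stop}) "
                f"exceeds recording bounds [0, {rec.n_samples})"
            )
        segments.append(rec.signal[:, start:stop])
        labels.append(label_map[code])
    if class_names is None:
        n_classes = max(label_map.values()) + 1
        inverse: dict[int, str] = {}
        for code, lab in label_map.items():
            inverse.setdefault(lab, code)
        class_names = [inverse.get(i, f"class{i}") for i in range(n_classes)]
    return TrialTensor(
        data=np.stack(segments) if segments else np.empty((0, rec.n_channels, t_len)),
        labels=np.asarray(labels, dtype=np.int64),
        fs=rec.fs,
        class_names=list(class_names),
    )


def make_split(
    trials: TrialTensor,
    n_train: int,
    seed: int,
    stratified: bool = True,
) -> SplitSpec:
    """Draw a uniformly random train/test partition, stratified by class.

    With ``stratified=True`` (default) the ``n_train`` training trials are
    apportioned across classes proportionally to class frequency (largest
    remainder for ties), so a balanced 60-trial set with ``n_train=40``
    yields 20 training trials per class.
    """
    m = trials.n_trials
    if not 0 < n_train < m:
        raise ValueError(f"n_train must lie in (0, {m}), got {n_train}")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(m)
        return SplitSpec(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)

    classes, counts = np.unique(trials.labels, return_counts=True)
    quota = n_train * counts / m
    take = np.floor(quota).astype(int)
    remainder = quota - take
    for k in np.argsort(-remainder)[: n_train - take.sum()]:
        take[k] += 1
    train_parts, test_parts = [], []
    for cls, n_cls in zip(classes, take):
        idx = np.flatnonzero(trials.labels == cls)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_cls])
        test_parts.append(perm[n_cls:])
    return SplitSpec(
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
        seed,
    )


__all__ = [
    "RawRecording",
    "TrialTensor",
    "SplitSpec",
    "EDFFormatError",
    "read_edf",
    "write_edf",
    "save_trials",
    "load_trials",
    "export_labels",
    "epoch_trials",
    "make_split",
    "replace",
]
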