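"""EEG containers, file I/O, windowed segmentation and label mapping.

Recordings are channels x samples matrices in microvolts.  Two on-disk
formats are supported:

* ``matrix-container`` — one raw little-endian float32 array (channels x
  samples, row-major) in ``<stem>.eeg`` plus a JSON sidecar ``<stem>.json``
  holding sampling rate, channel names, identifiers and labels/ratings.
* ``edf`` — European Data Format, read through MNE (optional dependency).

Channels are rows; sample indices are 0-based; windows are half-open
``[start, start + window_samples)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording", "EEGSegment", "SegmentDataset",
    "load_recording", "save_recording", "segment_recording",
    "dimension_label", "quadrant_label", "assemble_dataset",
    "save_dataset", "load_dataset",
    "TASKS", "SEED_CLASS_NAMES", "QUADRANT_NAMES",
]

#: Supported classification tasks: SEED-style discrete 3-class, the two
#: binary rating splits, and the 4-class rating-quadrant task.
TASKS = ("pnn", "arousal", "valence", "av")

SEED_CLASS_NAMES = ("negative", "neutral", "positive")
QUADRANT_NAMES = ("LALV", "LAHV", "HALV", "HAHV")
_SEED_LABEL_INDEX = {name: i for i, name in enumerate(SEED_CLASS_NAMES)}


@dataclass
class EEGRecording:
    """One trial of multichannel EEG with its metadata."""

    data: np.ndarray                      # (n_channels, n_samples), microvolts
    sampling_rate: int                    # Hz
    channel_names: list[str]
    subject_id: str = "S00"
    trial_id: str = "T00"
    discrete_label: str | None = None     # e.g. "positive" / "neutral" / "negative"
    ratings: dict[str, float] | None = None   # {"valence": 1-9, "arousal": 1-9}

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"channel mismatch: {self.data.shape[0]} data rows vs "
                f"{len(self.channel_names)} channel names")
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not (isinstance(self.sampling_rate, (int, np.integer)) and self.sampling_rate > 0):
            raise ValueError(f"sampling_rate must be a positive integer, got {self.sampling_rate!r}")
        if self.ratings is not None:
            for key, val in self.ratings.items():
                if not 1.0 <= float(val) <= 9.0:
                    raise ValueError(f"rating {key}={val} outside the 1-9 scale")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EEGSegment:
    """One fixed-length window cut from a recording."""

    data: np.ndarray          # (n_channels, window_samples)
    label: int                # class index in [0, n_classes)
    subject_id: str
    trial_id: str
    window_index: int


@dataclass
class SegmentDataset:
    """An ordered, homogeneous collection of labeled segments."""

    segments: list[EEGSegment]
    n_classes: int
    class_names: list[str]
    task: str = "pnn"
    sampling_rate: int | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.segments:
            shape = self.segments[0].data.shape
            for seg in self.segments:
                if seg.data.shape != shape:
                    raise ValueError("all segments must share channel count and window length")
                if not 0 <= seg.label < self.n_classes:
                    raise ValueError(f"label {seg.label} outside [0, {self.n_classes})")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_channels(self) -> int:
        return self.segments[0].data.shape[0]

    @property
    def window_samples(self) -> int:
        return self.segments[0].data.shape[1]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (n_segments, n_channels, window_samples) X and int label vector y."""
        X = np.stack([s.data for s in self.segments]).astype(np.float64)
        y = np.array([s.label for s in self.segments], dtype=np.int64)
        return X, y


# ---------------------------------------------------------------------------
# container / EDF I/O

def save_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write the matrix-container format: ``<stem>.eeg`` + ``<stem>.json``.

    The array is stored row-major as little-endian float32.
    """
    stem = Path(path).with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(rec.data, dtype="<f4").tofile(stem.with_suffix(".eeg"))
    sidecar = {
        "sampling_rate": int(rec.sampling_rate),
        "channel_names": list(rec.channel_names),
        "n_samples": int(rec.n_samples),
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
    }
    if rec.discrete_label is not None:
        sidecar["label"] = rec.discrete_label
    if rec.ratings is not None:
        if "valence" in rec.ratings:
            sidecar["valence"] = float(rec.ratings["valence"])
        if "arousal" in rec.ratings:
            sidecar["arousal"] = float(rec.ratings["arousal"])
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".eeg")


def _load_container(path: Path) -> EEGRecording:
    stem = path.with_suffix("")
    bin_path, json_path = stem.with_suffix(".eeg"), stem.with_suffix(".json")
    if not bin_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"matrix-container needs both {bin_path.name} and {json_path.name}")
    meta = json.loads(json_path.read_text())
    names = meta["channel_names"]
    raw = np.fromfile(bin_path, dtype="<f4")
    if len(names) == 0 or raw.size % len(names) != 0:
        raise ValueError(
            f"{bin_path.name}: {raw.size} float32 values do not divide into "
            f"{len(names)} channels listed in the sidecar")
    if "n_samples" in meta and raw.size != len(names) * int(meta["n_samples"]):
        raise ValueError(
            f"{bin_path.name}: array holds {raw.size} values but the sidecar "
            f"declares {len(names)} channels x {meta['n_samples']} samples")
    data = raw.reshape(len(names), -1)
    ratings = None
    if "valence" in meta or "arousal" in meta:
        ratings = {k: float(meta[k]) for k in ("valence", "arousal") if k in meta}
    return EEGRecording(
        data=data,
        sampling_rate=int(meta["sampling_rate"]),
        channel_names=list(names),
        subject_id=str(meta.get("subject_id", "S00")),
        trial_id=str(meta.get("trial_id", "T00")),
        discrete_label=meta.get("label"),
        ratings=ratings,
    )


def _load_edf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on install extras
        raise ImportError("reading EDF requires the 'mne' package (pip install sttcnn[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sf = raw.info["sfreq"]
    if abs(sf - round(sf)) > 1e-9:
        raise ValueError(f"non-integer sampling rate {sf} in {path.name}")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    return EEGRecording(
        data=data_uv,
        sampling_rate=int(round(sf)),
        channel_names=list(raw.ch_names),
        subject_id=path.stem,
        trial_id=path.stem,
    )


def load_recording(path: str | Path, format: str = "matrix-container") -> EEGRecording:
    """Read one recording from disk.

    Parameters
    ----------
    path
        For ``matrix-container``: either half of the ``.eeg``/``.json`` pair.
        For ``edf``: the ``.edf`` file.
    format
        ``"matrix-container"`` or ``"edf"``.
    """
    path = Path(path)
    if format == "matrix-container":
        return _load_container(path)
    if format == "edf":
        if not path.exists():
            raise FileNotFoundError(path)
        return _load_edf(path)
    raise ValueError(f"unknown format {format!r}; expected 'matrix-container' or 'edf'")


# ---------------------------------------------------------------------------
# segmentation and label mapping

def segment_recording(rec: EEGRecording, window_seconds: float = 3.0,
                      overlap_fraction: float = 0.0,
                      label: int | None = None) -> list[EEGSegment]:
    """Cut a recording into fixed-length windows.

    With zero overlap this yields exactly ``floor(n_samples / window_samples)``
    consecutive, non-overlapping windows; the trailing partial window is
    discarded.  A recording shorter than one window yields an empty list.

    ``label`` attaches an integer class index to each segment (use -1 for
    unlabeled data); when omitted, the SEED-style discrete label of the
    recording is used if present.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    ws_exact = window_seconds * rec.sampling_rate
    window_samples = int(round(ws_exact))
    if window_samples < 1 or abs(ws_exact - window_samples) > 1e-9:
        raise ValueError(
            f"window of {window_seconds} s at {rec.sampling_rate} Hz gives a "
            f"non-integer sample count {ws_exact}")
    if label is None:
        if rec.discrete_label is not None:
            label = _SEED_LABEL_INDEX.get(rec.discrete_label, -1)
        else:
            label = -1
    step = max(1, int(round(window_samples * (1.0 - overlap_fraction))))
    segments = []
    idx = 0
    for start in range(0, rec.n_samples - window_samples + 1, step):
        segments.append(EEGSegment(
            data=rec.data[:, start:start + window_samples],
            label=int(label),
            subject_id=rec.subject_id,
            trial_id=rec.trial_id,
            window_index=idx,
        ))
        idx += 1
    return segments


def save_dataset(dataset: SegmentDataset, path: str | Path) -> Path:
    """Persist a segmented dataset as one ``.npz`` archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    X, y = dataset.arrays()
    meta = {
        "n_classes": dataset.n_classes,
        "class_names": list(dataset.class_names),
        "task": dataset.task,
        "sampling_rate": dataset.sampling_rate,
        "channel_names": list(dataset.channel_names),
        "provenance": [[s.subject_id, s.trial_id, s.window_index] for s in dataset.segments],
    }
    np.savez(path, X=X.astype(np.float32), y=y,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))
    return path


def load_dataset(path: str | Path) -> SegmentDataset:
    """Inverse of :func:`save_dataset`."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        X, y = z["X"], z["y"]
    segments = [
        EEGSegment(data=X[i], label=int(y[i]), subject_id=sub, trial_id=trial,
                   window_index=int(widx))
        for i, (sub, trial, widx) in enumerate(meta["provenance"])
    ]
    return SegmentDataset(
        segments=segments, n_classes=meta["n_classes"],
        class_names=meta["class_names"], task=meta["task"],
        sampling_rate=meta["sampling_rate"], channel_names=meta["channel_names"],
    )


def dimension_label(rating: float, threshold: float = 5.0) -> int:
    """Binarise a 1-9 self-rating: 1 iff strictly above `threshold`, else 0."""
    rating = float(rating)
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside the 1-9 scale")
    return int(rating > threshold)


def quadrant_label(valence_rating: float, arousal_rating: float,
                   threshold: float = 5.0) -> int:
    """Map (valence, arousal) ratings to the four affect quadrants.

    0 = LALV, 1 = LAHV, 2 = HALV, 3 = HAHV (low/high arousal x low/high
    valence, arousal as the high-order bit).
    """
    v = dimension_label(valence_rating, threshold)
    a = dimension_label(arousal_rating, threshold)
    return 2 * a + v


def _task_label(rec: EEGRecording, task: str) -> int:
    if task == "pnn":
        if rec.discrete_label is None:
            raise ValueError(f"recording {rec.trial_id} lacks a discrete label for task 'pnn'")
        if rec.discrete_label not in _SEED_LABEL_INDEX:
            raise ValueError(f"unknown discrete label {rec.discrete_label!r}")
        return _SEED_LABEL_INDEX[rec.discrete_label]
    if rec.ratings is None:
        raise ValueError(f"recording {rec.trial_id} lacks ratings for task {task!r}")
    if task == "arousal":
        return dimension_label(rec.ratings["arousal"])
    if task == "valence":
        return dimension_label(rec.ratings["valence"])
    if task == "av":
        return quadrant_label(rec.ratings["valence"], rec.ratings["arousal"])
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def assemble_dataset(recordings: list[EEGRecording], task: str = "pnn",
                     window_seconds: float = 3.0,
                     overlap_fraction: float = 0.0) -> SegmentDataset:
    """Segment a homogeneous set of recordings into a labeled dataset."""
    if not recordings:
        raise ValueError("no recordings given")
    first = recordings[0]
    for rec in recordings:
        if rec.n_channels != first.n_channels:
            raise ValueError("recordings have heterogeneous channel counts")
        if rec.sampling_rate != first.sampling_rate:
            raise ValueError("recordings have heterogeneous sampling rates")
    if task == "pnn":
        n_classes, class_names = 3, list(SEED_CLASS_NAMES)
    elif task in ("arousal", "valence"):
        n_classes, class_names = 2, ["low", "high"]
    elif task == "av":
        n_classes, class_names = 4, list(QUADRANT_NAMES)
    else:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    segments: list[EEGSegment] = []
    for rec in recordings:
        lbl = _task_label(rec, task)
        segments.extend(segment_recording(rec, window_seconds, overlap_fraction, label=lbl))
    return SegmentDataset(
        segments=segments, n_classes=n_classes, class_names=class_names,
        task=task, sampling_rate=first.sampling_rate,
        channel_names=list(first.channel_names),
    )
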