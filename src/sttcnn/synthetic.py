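"""Class-conditional synthetic EEG with separately plantable spatial and
temporal discriminative structure.

Each trial is a channels x samples matrix built from three ingredients:

* a **spatial cue**: a 10 Hz carrier oscillation whose across-channel gain
  profile (a smooth topographic bump over the electrode index, one bump
  location per class) depends on the class, scaled by ``spatial_snr``;
* a **temporal cue**: a class-specific band-limited oscillation (theta /
  beta / ... center frequencies, one band per class) with a flat
  topography and random per-channel phases, scaled by ``temporal_snr``;
* background noise: 1/f^alpha ("pink") activity plus white Gaussian noise,
  the usual minimal model of resting EEG.

The two cues are orthogonally controllable: each class is identifiable
from either its topography or its oscillation band, so a single-branch
ablation sees a complete but noisier picture, while the dual-branch model
fuses two views of the same class structure.  Oscillation phases are
drawn per trial, making phase (not just the planted class structure) a
trial-level property, as in real recordings.

Setting ``spatial_snr=0`` removes every between-class spatial difference;
likewise ``temporal_snr=0`` for temporal differences; with both zero the
class-conditional distributions are identical and any classifier is at
chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (EEGRecording, SegmentDataset, assemble_dataset,
                 SEED_CLASS_NAMES, TASKS)

__all__ = ["SyntheticSpec", "generate_recording", "generate_dataset"]

#: Center frequencies (Hz) assigned to successive temporal class groups.
#: 10 Hz is reserved for the spatial-cue carrier.
_TEMPORAL_BANDS = (6.0, 20.0, 30.0, 3.0, 16.0, 26.0)
_SPATIAL_CARRIER_HZ = 10.0
#: Effect amplitude, microvolts of oscillation per unit SNR.
_AMP_PER_SNR = 10.0


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic study condition."""

    n_channels: int = 62
    sampling_rate: int = 200          # Hz
    trial_seconds: float = 60.0
    n_classes: int = 3
    spatial_snr: float = 1.0          # >= 0; 0 disables the spatial cue
    temporal_snr: float = 1.0         # >= 0; 0 disables the temporal cue
    pink_sigma: float = 15.0          # microvolt RMS of 1/f^alpha background
    pink_alpha: float = 1.0           # spectral exponent
    white_sigma: float = 5.0          # microvolt SD of sensor white noise
    seed: int = 0                     # master seed; per-trial streams derive from it

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.spatial_snr < 0 or self.temporal_snr < 0:
            raise ValueError("SNRs must be nonnegative")
        if self.sampling_rate <= 0 or self.n_channels < 1 or self.trial_seconds <= 0:
            raise ValueError("invalid geometry in SyntheticSpec")

    # -- canonical dataset regimes -----------------------------------------

    @classmethod
    def seed_like(cls, **kw) -> "SyntheticSpec":
        """62 channels, 200 Hz, 3 classes — the SEED recording regime."""
        return cls(**{"n_channels": 62, "sampling_rate": 200, "n_classes": 3, **kw})

    @classmethod
    def deap_like(cls, **kw) -> "SyntheticSpec":
        """32 channels, 128 Hz — the DEAP regime (classes set by the task)."""
        return cls(**{"n_channels": 32, "sampling_rate": 128, "n_classes": 2, **kw})

    @classmethod
    def reduced(cls, **kw) -> "SyntheticSpec":
        """Desk-scale regime for tests: 8 channels, 64 Hz, 15 s trials."""
        return cls(**{"n_channels": 8, "sampling_rate": 64, "trial_seconds": 15.0,
                      "n_classes": 3, **kw})

    # -- class structure -----------------------------------------------------

    def class_groups(self, class_index: int) -> tuple[int, int]:
        """(spatial_group, temporal_group) for a class — the identity map:
        every class carries its own topography and its own band."""
        if not 0 <= class_index < self.n_classes:
            raise ValueError(f"class_index {class_index} outside [0, {self.n_classes})")
        return class_index, class_index

    def topography(self, spatial_group: int) -> np.ndarray:
        """Smooth per-channel gain profile (Gaussian bump) for one class."""
        center = self.n_channels * (spatial_group + 1.0) / (self.n_classes + 1.0)
        width = max(self.n_channels / 8.0, 1.0)
        ch = np.arange(self.n_channels)
        return np.exp(-0.5 * ((ch - center) / width) ** 2)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                alpha: float, sigma: float) -> np.ndarray:
    """1/f^alpha noise per channel, synthesised in the frequency domain."""
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = 0.0  # no DC
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms * sigma


def _trial_rng(spec: SyntheticSpec, class_index: int, trial_seed: int) -> np.random.Generator:
    # Counter-based stream derivation: master seed plus (class, trial) spawn
    # key gives independent, reproducible streams per trial.
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(class_index, trial_seed)))


def generate_recording(spec: SyntheticSpec, class_index: int,
                       trial_seed: int = 0) -> EEGRecording:
    """Generate one labeled synthetic trial.

    Deterministic given ``(spec.seed, class_index, trial_seed)``.
    """
    sgrp, tgrp = spec.class_groups(class_index)
    rng = _trial_rng(spec, class_index, trial_seed)
    n_samples = int(round(spec.trial_seconds * spec.sampling_rate))
    t = np.arange(n_samples) / spec.sampling_rate

    x = _pink_noise(rng, spec.n_channels, n_samples, spec.pink_alpha, spec.pink_sigma)
    x += rng.standard_normal((spec.n_channels, n_samples)) * spec.white_sigma

    if spec.spatial_snr > 0:
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * _SPATIAL_CARRIER_HZ * t + phase)
        x += (spec.spatial_snr * _AMP_PER_SNR) * spec.topography(sgrp)[:, None] * carrier

    if spec.temporal_snr > 0:
        f = _TEMPORAL_BANDS[tgrp % len(_TEMPORAL_BANDS)]
        if f >= spec.sampling_rate / 2:
            raise ValueError(f"temporal band {f} Hz exceeds Nyquist for "
                             f"sampling rate {spec.sampling_rate}")
        phases = rng.uniform(0, 2 * np.pi, size=(spec.n_channels, 1))
        x += (spec.temporal_snr * _AMP_PER_SNR) * np.sin(
            2 * np.pi * f * t[None, :] + phases)

    label = None
    ratings = None
    if spec.n_classes == 3:
        label = SEED_CLASS_NAMES[class_index]
    elif spec.n_classes == 2:
        ratings = {"valence": 7.0 if class_index else 3.0,
                   "arousal": 7.0 if class_index else 3.0}
    elif spec.n_classes == 4:
        # quadrant code: arousal high-order bit, valence low-order
        ratings = {"valence": 7.0 if class_index & 1 else 3.0,
                   "arousal": 7.0 if class_index & 2 else 3.0}
    return EEGRecording(
        data=x.astype(np.float32),
        sampling_rate=spec.sampling_rate,
        channel_names=[f"CH{i + 1}" for i in range(spec.n_channels)],
        subject_id=f"SYN{spec.seed}",
        trial_id=f"c{class_index}t{trial_seed}",
        discrete_label=label,
        ratings=ratings,
    )


_TASK_CLASSES = {"pnn": 3, "arousal": 2, "valence": 2, "av": 4}


def generate_dataset(spec: SyntheticSpec, n_trials_per_class: int,
                     task: str = "pnn", window_seconds: float = 3.0) -> SegmentDataset:
    """Generate a balanced segmented dataset for one classification task.

    Trials are generated per class, then segmented with the standard
    windowing path, so provenance (subject / trial / window index) is
    retained on every segment.
    """
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if _TASK_CLASSES[task] != spec.n_classes:
        raise ValueError(
            f"task {task!r} needs {_TASK_CLASSES[task]} classes but spec has {spec.n_classes}")
    recordings = [
        generate_recording(spec, c, trial_seed=trial)
        for c in range(spec.n_classes)
        for trial in range(n_trials_per_class)
    ]
    return assemble_dataset(recordings, task=task, window_seconds=window_seconds)
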