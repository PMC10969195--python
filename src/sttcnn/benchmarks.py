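"""Frozen desk-scale study conditions for the synthetic benchmark suite.

Three protocols exercise the training stack end to end on generated data
(8 channels, 64 Hz, 15 s trials, 1 s windows; encoder width 16, 8 heads,
32 conv kernels):

* **overfit** — strong planted signal (SNR 3), 64 segments: the full model
  must fit its training set perfectly within 100 epochs.
* **null** — SNR 0: held-out accuracy must stay inside the 95% binomial
  interval around chance, since the class-conditional distributions are
  identical.
* **ablation** — moderate planted signal (SNR 0.5, about -10 dB
  effect-to-background power) on both axes, 3-fold CV over 270 segments:
  the regime where two noisy views beat one, probing the qualitative
  ordering full / dual-no-CNN / single-branch.

These values are the package's reduced problem sizes; they are deliberately
centralised so the test suite and the acceptance script measure the same
conditions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .evaluation import CVReport
from .model import ModelConfig, VARIANTS
from .synthetic import SyntheticSpec, generate_dataset
from .training import TrainConfig, cross_validate, make_folds, train_fold

__all__ = ["reduced_model_config", "reduced_train_config", "run_overfit",
           "run_null", "run_ablation", "run_single_cue",
           "binomial_chance_interval"]

_N_CHANNELS = 8
_WINDOW_SAMPLES = 64          # 1 s at 64 Hz
_TRIALS_PER_CLASS = 6


def reduced_model_config(variant: str = "st-tcnn", dropout: float = 0.1) -> ModelConfig:
    return ModelConfig(n_channels=_N_CHANNELS, window_samples=_WINDOW_SAMPLES,
                       n_classes=3, variant=variant, d_model=16, n_heads=8,
                       conv_channels=32, dropout=dropout)


def reduced_train_config(seed: int, **kw) -> TrainConfig:
    defaults = dict(k_folds=3, learning_rate=1e-3, batch_size=64, max_epochs=42,
                    l2_lambda=1e-4, seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


def _dataset(spatial_snr: float, temporal_snr: float, data_seed: int,
             trials: int = _TRIALS_PER_CLASS):
    spec = SyntheticSpec.reduced(spatial_snr=spatial_snr, temporal_snr=temporal_snr,
                                 seed=data_seed)
    return generate_dataset(spec, n_trials_per_class=trials, task="pnn",
                            window_seconds=1.0)


def run_overfit(seed: int) -> dict:
    """Fit the full model to a 64-segment strong-signal set; report the best
    training accuracy reached within 100 epochs."""
    ds = _dataset(3.0, 3.0, data_seed=1000 + seed, trials=2)
    ds.segments = ds.segments[:64]
    cfg = reduced_model_config(dropout=0.0)
    tc = reduced_train_config(seed, max_epochs=100, l2_lambda=0.0,
                              stop_at_train_accuracy=1.0,
                              track_train_accuracy=True)
    # single split: train on two folds, the held-out fold is irrelevant here
    assignment = make_folds(ds, k=4, seed=seed)
    res = train_fold(ds, assignment, fold_index=0, model_cfg=cfg, train_cfg=tc)
    return {
        "train_accuracy": max(res.train_accuracy_history),
        "epochs_used": len(res.loss_history),
        "loss_history": res.loss_history,
        "n_train": int((assignment != 0).sum()),
    }


def binomial_chance_interval(n: int, p_chance: float, level: float = 0.95):
    """Acceptance band for an accuracy estimated from n chance-level trials."""
    lo, hi = stats.binom.interval(level, n, p_chance)
    return lo / n, hi / n


def run_null(seed: int) -> dict:
    """Train on signal-free data; held-out accuracy should be chance."""
    ds = _dataset(0.0, 0.0, data_seed=2000 + seed)
    cfg = reduced_model_config()
    tc = reduced_train_config(seed, max_epochs=15)
    assignment = make_folds(ds, k=3, seed=seed)
    res = train_fold(ds, assignment, fold_index=0, model_cfg=cfg, train_cfg=tc)
    n_test = int(res.confusion.sum())
    lo, hi = binomial_chance_interval(n_test, 1.0 / ds.n_classes)
    return {"heldout_accuracy": res.test_accuracy, "n_test": n_test,
            "chance": 1.0 / ds.n_classes, "ci_low": lo, "ci_high": hi}


def run_single_cue(seed: int, axis: str) -> dict:
    """Train the matching single-branch variant on data carrying only one
    cue, planted strongly (SNR 3): spatial -> s-t, temporal -> t-t.

    Uses one held-out fold; returns the accuracy and its chance band.
    """
    if axis == "spatial":
        variant, snrs = "s-t", (3.0, 0.0)
    elif axis == "temporal":
        variant, snrs = "t-t", (0.0, 3.0)
    else:
        raise ValueError("axis must be 'spatial' or 'temporal'")
    ds = _dataset(snrs[0], snrs[1], data_seed=100 + seed)
    assignment = make_folds(ds, k=3, seed=seed)
    res = train_fold(ds, assignment, 0, reduced_model_config(variant),
                     reduced_train_config(seed))
    n_test = int(res.confusion.sum())
    lo, hi = binomial_chance_interval(n_test, 1.0 / ds.n_classes)
    return {"variant": variant, "heldout_accuracy": res.test_accuracy,
            "n_test": n_test, "chance_upper": hi}


def run_ablation(seed: int, spatial_snr: float = 0.5, temporal_snr: float = 0.5,
                 variants: tuple = VARIANTS) -> dict[str, CVReport]:
    """Cross-validate the requested variants on one planted-signal dataset."""
    ds = _dataset(spatial_snr, temporal_snr, data_seed=100 + seed)
    out: dict[str, CVReport] = {}
    for variant in variants:
        out[variant] = cross_validate(ds, reduced_model_config(variant),
                                      reduced_train_config(seed))
    return out
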