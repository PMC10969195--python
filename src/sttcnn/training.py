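"""Stratified k-fold cross-validated training with Adam and
cross-entropy + L2 loss.

The reference protocol splits each subject's segments into ten folds,
trains on nine and tests on the held-out one, rotating; the average
accuracy over folds is the headline number.  Fold assignment is
stratified by class and deterministic given the seed.  Because
segment-level splitting lets windows from one trial land in both train
and test folds (which inflates accuracy through temporal
autocorrelation), a trial-grouped mode is offered as a more conservative
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold

from . import autodiff as ad
from .autodiff import Tensor
from .io import SegmentDataset
from .model import ModelConfig, forward_logits, init_params, is_weight
from .evaluation import CVReport, confusion_matrix, metrics_from_confusion

__all__ = ["TrainConfig", "FoldResult", "make_folds", "loss", "train_fold",
           "cross_validate", "evaluate_params", "Adam"]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (Adam, cross-entropy + L2)."""

    k_folds: int = 10
    learning_rate: float = 1e-4
    batch_size: int = 128
    l2_lambda: float = 1e-4
    max_epochs: int = 100
    early_stop_patience: int | None = None   # epochs without train-loss improvement
    stop_at_train_accuracy: float | None = None  # e.g. 1.0 stops once fit is perfect
    track_train_accuracy: bool = False       # per-epoch eval-mode training accuracy
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    group_by_trial: bool = False
    precision: str = "float32"         # arithmetic width for the training loop
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FoldResult:
    """Outcome of training on k-1 folds and testing on the held-out one."""

    fold_index: int
    test_accuracy: float
    confusion: np.ndarray              # (n_classes, n_classes) held-out counts
    loss_history: list[float]          # mean training loss per epoch
    train_accuracy_history: list[float]
    params: dict[str, Tensor]


class Adam:
    """Standard Adam with bias correction, over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def make_folds(dataset: SegmentDataset, k: int = 10, seed: int = 0,
               group_by_trial: bool = False) -> np.ndarray:
    """Stratified partition into k disjoint, exhaustive folds.

    Returns an integer fold index per segment.  With ``group_by_trial``
    all segments of one trial stay in the same fold (stratified group
    k-fold); otherwise segments are assigned individually.
    """
    _, y = dataset.arrays()
    if len(y) < k:
        raise ValueError(f"dataset of {len(y)} segments cannot form {k} folds")
    assignment = np.full(len(y), -1, dtype=np.int64)
    if group_by_trial:
        groups = np.array([f"{s.subject_id}/{s.trial_id}" for s in dataset.segments])
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y)
    for fold, (_, test_idx) in enumerate(split):
        assignment[test_idx] = fold
    return assignment


def loss(logits, labels: np.ndarray, params: dict[str, Tensor] | None = None,
         l2_lambda: float = 0.0) -> Tensor:
    """Mean cross-entropy plus ``l2_lambda * sum(w^2)`` over weight matrices.

    Biases and layer-norm affine parameters are exempt from the penalty.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float64))
    labels = np.asarray(labels)
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {n}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"label outside [0, {c})")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    ce = ad.scale(ad.sum_(ad.mul(ad.log_softmax(logits, axis=-1), Tensor(onehot))), -1.0 / n)
    if params and l2_lambda > 0:
        penalty = None
        for name, p in params.items():
            if not is_weight(name):
                continue
            term = ad.sum_(ad.mul(p, p))
            penalty = term if penalty is None else ad.add(penalty, term)
        if penalty is not None:
            ce = ad.add(ce, ad.scale(penalty, l2_lambda))
    return ce


def evaluate_params(X: np.ndarray, y: np.ndarray, cfg: ModelConfig,
                    params: dict[str, Tensor], batch_size: int = 128
                    ) -> tuple[float, np.ndarray]:
    """Deterministic eval-mode accuracy and per-segment predicted labels."""
    preds = []
    for start in range(0, len(X), batch_size):
        logits = forward_logits(X[start:start + batch_size], cfg, params, mode="eval")
        preds.append(np.argmax(logits.data, axis=1))
    pred = np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)
    return float(np.mean(pred == y)) if len(y) else float("nan"), pred


def train_fold(dataset: SegmentDataset, fold_assignment: np.ndarray, fold_index: int,
               model_cfg: ModelConfig, train_cfg: TrainConfig) -> FoldResult:
    """Train on all folds except ``fold_index`` and test on it."""
    with ad.use_dtype(np.dtype(train_cfg.precision)):
        return _train_fold(dataset, fold_assignment, fold_index, model_cfg, train_cfg)


def _train_fold(dataset: SegmentDataset, fold_assignment: np.ndarray, fold_index: int,
                model_cfg: ModelConfig, train_cfg: TrainConfig) -> FoldResult:
    X, y = dataset.arrays()
    test_mask = fold_assignment == fold_index
    if not test_mask.any():
        raise ValueError(f"fold {fold_index} is empty")
    if model_cfg.input_standardize:
        # standardization is per segment, so it can be done once up front
        from .model import standardize_segments
        import dataclasses
        X = standardize_segments(X)
        model_cfg = dataclasses.replace(model_cfg, input_standardize=False)
    Xtr, ytr = X[~test_mask], y[~test_mask]
    Xte, yte = X[test_mask], y[test_mask]

    ss = np.random.SeedSequence(train_cfg.seed, spawn_key=(fold_index,))
    init_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    rng = np.random.default_rng(ss)
    params = init_params(model_cfg, seed=init_seed)
    opt = Adam(params, train_cfg.learning_rate, train_cfg.beta1,
               train_cfg.beta2, train_cfg.adam_eps)

    loss_history: list[float] = []
    acc_history: list[float] = []
    best_loss, stall = np.inf, 0
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        batch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            logits = forward_logits(Xtr[idx], model_cfg, params, mode="train", rng=rng)
            L = loss(logits, ytr[idx], params, train_cfg.l2_lambda)
            if not np.isfinite(L.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"fold {fold_index} (lr={train_cfg.learning_rate})")
            opt.zero_grad()
            L.backward()
            opt.step()
            batch_losses.append(float(L.data))
        epoch_loss = float(np.mean(batch_losses))
        loss_history.append(epoch_loss)
        if train_cfg.track_train_accuracy or train_cfg.stop_at_train_accuracy is not None:
            train_acc, _ = evaluate_params(Xtr, ytr, model_cfg, params,
                                           train_cfg.batch_size)
            acc_history.append(train_acc)
            if (train_cfg.stop_at_train_accuracy is not None
                    and train_acc >= train_cfg.stop_at_train_accuracy):
                break
        if train_cfg.early_stop_patience is not None:
            if epoch_loss < best_loss - 1e-6:
                best_loss, stall = epoch_loss, 0
            else:
                stall += 1
                if stall >= train_cfg.early_stop_patience:
                    break

    test_acc, pred = evaluate_params(Xte, yte, model_cfg, params, train_cfg.batch_size)
    cm = confusion_matrix(yte, pred, dataset.n_classes)
    return FoldResult(fold_index=fold_index, test_accuracy=test_acc, confusion=cm,
                      loss_history=loss_history, train_accuracy_history=acc_history,
                      params=params)


def cross_validate(dataset: SegmentDataset, model_cfg: ModelConfig,
                   train_cfg: TrainConfig, keep_params: bool = False) -> CVReport:
    """Run all k folds; every segment is tested exactly once."""
    assignment = make_folds(dataset, train_cfg.k_folds, train_cfg.seed,
                            train_cfg.group_by_trial)
    fold_accs: list[float] = []
    pooled = np.zeros((dataset.n_classes, dataset.n_classes), dtype=np.int64)
    folds: list[FoldResult] = []
    for fold in range(train_cfg.k_folds):
        res = train_fold(dataset, assignment, fold, model_cfg, train_cfg)
        fold_accs.append(res.test_accuracy)
        pooled += res.confusion
        if not keep_params:
            res.params = {}
        folds.append(res)
    accs = np.array(fold_accs)
    return CVReport(
        fold_accuracies=fold_accs,
        mean_accuracy=float(accs.mean()),
        variance=float(accs.var()),          # population variance over folds
        confusion=pooled,
        metrics=metrics_from_confusion(pooled),
        variant=model_cfg.variant,
        task=dataset.task,
        fold_results=folds,
    )
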