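"""The dual-branch spatial-temporal transformer + CNN classifier.

A 3 s EEG segment (channels x samples) is fed to the network in two
arrangements at once: the **spatial branch** treats each channel as a
token (its feature vector is the window's time course) so self-attention
ranges across electrode positions, and the **temporal branch** treats
each time point as a token (feature vector = the instantaneous
cross-channel pattern) so attention ranges across time.  Each branch
linearly embeds its tokens to ``d_model``, adds a sinusoidal positional
encoding, and applies transformer encoder blocks (multi-head attention
and a position-wise feed-forward network, each with residual connection
and post-norm layer normalisation).  The two token maps are concatenated
along the token axis into one 2-D feature map and aggregated by a small
CNN head (two same-padded 3x3 convolutions, 2x2 max pooling, a fully
connected layer and softmax).

Four variants support the ablation study:

========  ==================================================
st-tcnn   both branches + CNN head (the full model)
st-t      both branches, feature map flattened straight into the FC layer
s-t       spatial branch only + CNN head
t-t       temporal branch only + CNN head
========  ==================================================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "VARIANTS", "ModelConfig", "AttentionResult", "PositionalEncodingTable",
    "positional_encoding", "scaled_dot_product_attention", "multi_head_attention",
    "encoder_block", "branch_forward", "predict", "forward_logits",
    "init_params", "parameter_count", "standardize_segments",
    "save_checkpoint", "load_checkpoint",
]

VARIANTS = ("st-tcnn", "st-t", "s-t", "t-t")

_CHECKPOINT_SCHEMA = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters; the variant selects branches and head."""

    n_channels: int
    window_samples: int
    n_classes: int
    variant: str = "st-tcnn"
    d_model: int = 64
    n_heads: int = 8                  # "h" of the multi-head attention
    n_encoder_layers: int = 1         # encoder blocks per branch
    ff_dim: int | None = None         # defaults to 4 * d_model
    dropout: float = 0.3
    conv_channels: int = 64           # kernels per convolution layer
    conv_kernel_size: int = 3
    pool_size: int = 2
    input_standardize: bool = True    # per-segment, per-channel z-scoring
    use_positional_encoding: bool = True
    ln_eps: float = 1e-5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.d_model % self.n_heads != 0:
            raise ValueError(f"d_model {self.d_model} not divisible by n_heads {self.n_heads}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.ff_dim is None:
            self.ff_dim = 4 * self.d_model

    # -- variant structure ---------------------------------------------------

    @property
    def branches(self) -> tuple[str, ...]:
        return {"st-tcnn": ("spatial", "temporal"), "st-t": ("spatial", "temporal"),
                "s-t": ("spatial",), "t-t": ("temporal",)}[self.variant]

    @property
    def has_cnn_head(self) -> bool:
        return self.variant != "st-t"

    def seq_len(self, branch: str) -> int:
        return self.n_channels if branch == "spatial" else self.window_samples

    def token_features(self, branch: str) -> int:
        return self.window_samples if branch == "spatial" else self.n_channels

    @property
    def map_height(self) -> int:
        """Token-axis height of the concatenated feature map."""
        return sum(self.seq_len(b) for b in self.branches)

    @property
    def fc_in_dim(self) -> int:
        h, w = self.map_height, self.d_model
        if not self.has_cnn_head:
            return h * w
        return (h // self.pool_size) * (w // self.pool_size) * self.conv_channels


@dataclass
class AttentionResult:
    """Output of one scaled dot-product attention evaluation."""

    output: np.ndarray    # (n, d_v)
    weights: np.ndarray   # (n, m), rows nonnegative and summing to 1


@dataclass
class PositionalEncodingTable:
    """Sinusoidal position table; every (sin, cos) pair lies on the unit circle."""

    table: np.ndarray     # (max_pos, d)


def positional_encoding(max_pos: int, d: int) -> PositionalEncodingTable:
    """Sinusoidal positional encoding.

    ``table[pos, 2i] = sin(pos / 10000^(2i/d))`` and
    ``table[pos, 2i+1] = cos(pos / 10000^(2i/d))``.
    """
    if max_pos < 1:
        raise ValueError("max_pos must be >= 1")
    if d < 2 or d % 2 != 0:
        raise ValueError(f"embedding dimension must be even and >= 2, got {d}")
    pos = np.arange(max_pos, dtype=np.float64)[:, None]
    two_i = np.arange(0, d, 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, two_i / d)
    table = np.empty((max_pos, d))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return PositionalEncodingTable(table=table)


# ---------------------------------------------------------------------------
# attention

def scaled_dot_product_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                                 d_k: int | None = None) -> AttentionResult:
    """``softmax(Q K^T / sqrt(d_k)) V`` for 2-D query/key/value matrices."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValueError("Q, K, V must be 2-D matrices")
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ValueError(f"incompatible shapes Q{Q.shape} K{K.shape} V{V.shape}")
    if d_k is None:
        d_k = Q.shape[1]
    scores = Q @ K.T / math.sqrt(d_k)
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    return AttentionResult(output=w @ V, weights=w)


def _batched_mha(X: Tensor, p: dict[str, Tensor], h: int) -> Tensor:
    """Multi-head self-attention on (B, s, d_model) via head-folded matmuls."""
    B, s, d = X.shape
    d_k = d // h

    def heads(W, b):
        proj = ad.add(ad.matmul(X, W), b)                       # (B, s, d)
        return ad.transpose(ad.reshape(proj, (B, s, h, d_k)), (0, 2, 1, 3))

    Q, K, V = heads(p["Wq"], p["bq"]), heads(p["Wk"], p["bk"]), heads(p["Wv"], p["bv"])
    scores = ad.scale(ad.matmul(Q, ad.transpose(K, (0, 1, 3, 2))), 1.0 / math.sqrt(d_k))
    A = ad.softmax(scores, axis=-1)                             # (B, h, s, s)
    ctx = ad.matmul(A, V)                                       # (B, h, s, d_k)
    ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, s, d))
    return ad.add(ad.matmul(ctx, p["Wo"]), p["bo"])


def multi_head_attention(X: np.ndarray, params: dict[str, np.ndarray], h: int) -> np.ndarray:
    """Multi-head self-attention on one (seq_len, d_model) matrix.

    ``params`` holds the stacked projections ``Wq/Wk/Wv/Wo`` (each
    d_model x d_model) and biases ``bq/bk/bv/bo``; head ``j`` uses columns
    ``[j*d_k, (j+1)*d_k)`` of the stacked projections.
    """
    X = np.asarray(X, dtype=np.float64)
    d = X.shape[1]
    if d % h != 0:
        raise ValueError(f"d_model {d} not divisible by h={h}")
    tp = {k: Tensor(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
    out = _batched_mha(Tensor(X[None]), tp, h)
    return out.data[0]


# ---------------------------------------------------------------------------
# encoder block and branches

def _layer_norm_affine(X: Tensor, g: Tensor, b: Tensor, eps: float) -> Tensor:
    return ad.add(ad.mul(ad.layer_norm(X, eps=eps), g), b)


def _dropout(X: Tensor, rate: float, mode: str, rng: np.random.Generator | None) -> Tensor:
    if mode != "train" or rate == 0.0:
        return X
    if rng is None:
        raise ValueError("train mode with dropout requires an RNG")
    return ad.mul(X, Tensor(ad.dropout_mask(X.shape, rate, rng)))


def _encoder_block(X: Tensor, p: dict[str, Tensor], cfg: ModelConfig,
                   mode: str, rng) -> Tensor:
    att = _dropout(_batched_mha(X, p, cfg.n_heads), cfg.dropout, mode, rng)
    Y1 = _layer_norm_affine(ad.add(X, att), p["ln1_g"], p["ln1_b"], cfg.ln_eps)
    ff = ad.add(ad.matmul(ad.relu(ad.add(ad.matmul(Y1, p["W1"]), p["b1"])), p["W2"]), p["b2"])
    ff = _dropout(ff, cfg.dropout, mode, rng)
    return _layer_norm_affine(ad.add(Y1, ff), p["ln2_g"], p["ln2_b"], cfg.ln_eps)


def encoder_block(X: np.ndarray, cfg: ModelConfig, params: dict[str, np.ndarray],
                  mode: str = "eval", rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply one transformer encoder block to a (seq_len, d_model) matrix."""
    if not np.all(np.isfinite(X)):
        raise ValueError("encoder input must be finite")
    tp = {k: Tensor(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
    return _encoder_block(Tensor(np.asarray(X, dtype=np.float64)[None]),
                          tp, cfg, mode, rng).data[0]


def standardize_segments(X: np.ndarray) -> np.ndarray:
    """Per-segment, per-channel z-scoring over time of a (B, C, T) batch."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    return (X - mu) / (sd + 1e-8)


def _branch_tokens(X: np.ndarray, branch: str) -> np.ndarray:
    """Arrange a (B, C, T) batch as (B, seq_len, token_features)."""
    if branch == "spatial":
        return X                       # tokens = channels
    if branch == "temporal":
        return X.transpose(0, 2, 1)    # tokens = time points
    raise ValueError(f"branch must be 'spatial' or 'temporal', got {branch!r}")


def _forward_branch(Xstd: np.ndarray, branch: str, cfg: ModelConfig,
                    params: dict[str, Tensor], mode: str, rng) -> Tensor:
    prefix = "s" if branch == "spatial" else "t"
    tokens = Tensor(_branch_tokens(Xstd, branch))
    emb = ad.add(ad.matmul(tokens, params[f"{prefix}.embed.W"]), params[f"{prefix}.embed.b"])
    if cfg.use_positional_encoding:
        pe = positional_encoding(cfg.seq_len(branch), cfg.d_model).table
        emb = ad.add(emb, Tensor(pe))
    out = emb
    for layer in range(cfg.n_encoder_layers):
        blk = {name.rsplit(".", 1)[-1]: t for name, t in params.items()
               if name.startswith(f"{prefix}.enc{layer}.")}
        out = _encoder_block(out, blk, cfg, mode, rng)
    return out


def branch_forward(segment_batch: np.ndarray, branch: str, cfg: ModelConfig,
                   params: dict[str, "Tensor | np.ndarray"], mode: str = "eval",
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Encode a (batch, n_channels, window_samples) batch with one branch.

    Returns (batch, seq_len, d_model): seq_len = n_channels for the spatial
    branch, window_samples for the temporal branch.
    """
    X = np.asarray(segment_batch, dtype=np.float64)
    if X.ndim != 3 or X.shape[1] != cfg.n_channels or X.shape[2] != cfg.window_samples:
        raise ValueError(f"expected (batch, {cfg.n_channels}, {cfg.window_samples}), got {X.shape}")
    if cfg.input_standardize:
        X = standardize_segments(X)
    tp = {k: (v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64)))
          for k, v in params.items()}
    return _forward_branch(X, branch, cfg, tp, mode, rng).data


# ---------------------------------------------------------------------------
# full forward pass

def forward_logits(segment_batch: np.ndarray, cfg: ModelConfig,
                   params: dict[str, Tensor], mode: str = "eval",
                   rng: np.random.Generator | None = None) -> Tensor:
    """Class logits (pre-softmax) for a (B, C, T) batch; differentiable."""
    X = np.asarray(segment_batch, dtype=np.float64)
    if X.ndim != 3 or X.shape[1] != cfg.n_channels or X.shape[2] != cfg.window_samples:
        raise ValueError(f"expected (batch, {cfg.n_channels}, {cfg.window_samples}), got {X.shape}")
    if cfg.input_standardize:
        X = standardize_segments(X)
    B = X.shape[0]
    maps = [_forward_branch(X, br, cfg, params, mode, rng) for br in cfg.branches]
    fmap = maps[0] if len(maps) == 1 else ad.concat(maps, axis=1)   # (B, H, d_model)

    if cfg.has_cnn_head:
        # the concatenated token map is treated as a 1-channel H x W image,
        # kept in token layout (B, H*W, channels) throughout
        H, W = cfg.map_height, cfg.d_model
        k = cfg.conv_kernel_size
        img = ad.reshape(fmap, (B, H * W, 1))
        c1 = ad.relu(ad.conv2d_tokens(img, params["head.conv1.W"],
                                      params["head.conv1.b"], H, W, k))
        c2 = ad.relu(ad.conv2d_tokens(c1, params["head.conv2.W"],
                                      params["head.conv2.b"], H, W, k))
        pooled = ad.maxpool2x2_tokens(c2, H, W)
        flat = ad.reshape(pooled, (B, cfg.fc_in_dim))
    else:
        flat = ad.reshape(fmap, (B, cfg.fc_in_dim))

    flat = _dropout(flat, cfg.dropout, mode, rng)
    return ad.add(ad.matmul(flat, params["head.fc.W"]), params["head.fc.b"])


def predict(segment_batch: np.ndarray, cfg: ModelConfig,
            params: dict[str, "Tensor | np.ndarray"], mode: str = "eval",
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Class probabilities, (batch, n_classes); each row sums to 1."""
    tp = {k: (v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64)))
          for k, v in params.items()}
    logits = forward_logits(segment_batch, cfg, tp, mode, rng)
    return ad.softmax(logits, axis=-1).data


# ---------------------------------------------------------------------------
# parameters

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    a = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


def init_params(cfg: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Glorot-uniform initial parameters; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    d, ff = cfg.d_model, cfg.ff_dim
    p: dict[str, np.ndarray] = {}
    for branch in cfg.branches:
        pre = "s" if branch == "spatial" else "t"
        feat = cfg.token_features(branch)
        p[f"{pre}.embed.W"] = _glorot(rng, feat, d, (feat, d))
        p[f"{pre}.embed.b"] = np.zeros(d)
        for layer in range(cfg.n_encoder_layers):
            base = f"{pre}.enc{layer}"
            for proj in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{base}.{proj}"] = _glorot(rng, d, d, (d, d))
            for bias in ("bq", "bk", "bv", "bo"):
                p[f"{base}.{bias}"] = np.zeros(d)
            p[f"{base}.W1"] = _glorot(rng, d, ff, (d, ff))
            p[f"{base}.b1"] = np.zeros(ff)
            p[f"{base}.W2"] = _glorot(rng, ff, d, (ff, d))
            p[f"{base}.b2"] = np.zeros(d)
            p[f"{base}.ln1_g"] = np.ones(d)
            p[f"{base}.ln1_b"] = np.zeros(d)
            p[f"{base}.ln2_g"] = np.ones(d)
            p[f"{base}.ln2_b"] = np.zeros(d)
    if cfg.has_cnn_head:
        # conv weights in im2col form: (kernel offsets x in-channels, out-channels)
        k2 = cfg.conv_kernel_size ** 2
        c = cfg.conv_channels
        p["head.conv1.W"] = _glorot(rng, k2, c, (k2, c))
        p["head.conv1.b"] = np.zeros(c)
        p["head.conv2.W"] = _glorot(rng, c * k2, c, (k2 * c, c))
        p["head.conv2.b"] = np.zeros(c)
    p["head.fc.W"] = _glorot(rng, cfg.fc_in_dim, cfg.n_classes, (cfg.fc_in_dim, cfg.n_classes))
    p["head.fc.b"] = np.zeros(cfg.n_classes)
    return {name: Tensor(arr, requires_grad=True, name=name) for name, arr in p.items()}


def parameter_count(cfg: ModelConfig) -> int:
    """Total trainable scalar count — a pure function of the config."""
    return sum(t.data.size for t in init_params(cfg, seed=0).values())


def is_weight(name: str) -> bool:
    """True for parameters that enter the L2 penalty (weight matrices only:
    biases and layer-norm affine parameters are exempt)."""
    return name.rsplit(".", 1)[-1].startswith("W")


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path: str | Path, cfg: ModelConfig, params: dict[str, Tensor]) -> Path:
    """Write config + named parameter arrays to a single ``.npz`` archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"schema": _CHECKPOINT_SCHEMA, "config": asdict(cfg)}
    arrays = {f"param/{k}": v.data for k, v in params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[ModelConfig, dict[str, Tensor]]:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("schema", 0) > _CHECKPOINT_SCHEMA:
            raise ValueError(f"checkpoint schema {meta['schema']} is newer than supported")
        cfg = ModelConfig(**meta["config"])
        params = {k[len("param/"):]: Tensor(z[k], requires_grad=True, name=k[len("param/"):])
                  for k in z.files if k.startswith("param/")}
    return cfg, params
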