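"""The trainable sequence encoder.

An encoder-only, pre-norm transformer in the T5 style: RMS normalization
without biases, bias-free linear maps, ReLU feed-forward blocks, learned
relative-position attention biases shared across layers, and input/output
embeddings tied so the per-position vocabulary distribution is a softmax
over similarities to the residue embeddings.  The default configuration
has six layers; test configurations use hidden sizes of 32-64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, parameter, constant
from .sequence_io import TokenSequence, Vocabulary, DEFAULT_MAX_LENGTH

_NEG_INF = -1e9
_NORM_EPS = 1e-6


@dataclass(frozen=True)
class StudentConfig:
    num_layers: int = 6
    hidden_dim: int = 256
    num_heads: int = 4
    feedforward_dim: int = 512
    vocab_size: int = 23
    max_length: int = DEFAULT_MAX_LENGTH
    dropout: float = 0.0
    rel_pos_buckets: int = 32
    rel_pos_max_distance: int = 128

    def __post_init__(self):
        if self.num_layers < 0:
            raise ValueError("num_layers must be >= 0")
        if self.hidden_dim % self.num_heads != 0:
            raise ValueError("num_heads must divide hidden_dim")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be a probability below 1")


@dataclass(frozen=True)
class StudentOutput:
    """Per-position hidden vectors and vocabulary distributions."""

    hidden: np.ndarray  # N x hidden_dim
    dists: np.ndarray  # N x V, rows sum to 1
    log_dists: np.ndarray  # N x V, log of dists (kept for numerical work)


def relative_position_bucket(relative_position: np.ndarray, num_buckets: int,
                             max_distance: int) -> np.ndarray:
    """T5-style bidirectional bucketing of signed relative positions."""
    num_buckets //= 2
    ret = (relative_position > 0).astype(np.int64) * num_buckets
    n = np.abs(relative_position)
    max_exact = num_buckets // 2
    is_small = n < max_exact
    # logarithmic buckets for larger distances
    with np.errstate(divide="ignore"):
        val_if_large = max_exact + (
            np.log(np.maximum(n, 1) / max_exact)
            / np.log(max_distance / max_exact)
            * (num_buckets - max_exact)
        ).astype(np.int64)
    val_if_large = np.minimum(val_if_large, num_buckets - 1)
    return ret + np.where(is_small, n, val_if_large)


def _rms_norm(x: Tensor, gain: Tensor) -> Tensor:
    scale = (x * x).mean(axis=-1, keepdims=True) + _NORM_EPS
    return x * scale**-0.5 * gain


class StudentModel:
    """Holds parameters and runs forward passes; pure NumPy/autodiff."""

    def __init__(self, config: StudentConfig, vocab: Vocabulary | None = None,
                 seed: int = 0):
        self.config = config
        self.vocab = vocab or Vocabulary()
        if self.vocab.size != config.vocab_size:
            raise ValueError(
                f"config vocab_size {config.vocab_size} != vocabulary size "
                f"{self.vocab.size}"
            )
        rng = np.random.default_rng(seed)
        d, dff = config.hidden_dim, config.feedforward_dim
        sd = d**-0.5
        self.embedding = parameter(rng.standard_normal((config.vocab_size, d)) * sd)
        self.layers: list[dict[str, Tensor]] = []
        for _ in range(config.num_layers):
            self.layers.append({
                "attn_norm": parameter(np.ones(d)),
                "wq": parameter(rng.standard_normal((d, d)) * sd),
                "wk": parameter(rng.standard_normal((d, d)) * sd),
                "wv": parameter(rng.standard_normal((d, d)) * sd),
                "wo": parameter(rng.standard_normal((d, d)) * sd),
                "ffn_norm": parameter(np.ones(d)),
                "wi": parameter(rng.standard_normal((d, dff)) * sd),
                "wf": parameter(rng.standard_normal((dff, d)) * dff**-0.5),
            })
        if config.num_layers > 0:
            self.final_norm = parameter(np.ones(d))
            self.rel_bias = parameter(
                np.zeros((config.rel_pos_buckets, config.num_heads))
            )
        else:
            self.final_norm = None
            self.rel_bias = None
        self._bucket_cache: dict[int, np.ndarray] = {}

    # -- parameter bookkeeping -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [self.embedding]
        for layer in self.layers:
            params.extend(layer.values())
        if self.final_norm is not None:
            params.extend([self.final_norm, self.rel_bias])
        return params

    def parameter_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    # -- forward ---------------------------------------------------------------

    def _buckets(self, n: int) -> np.ndarray:
        if n not in self._bucket_cache:
            pos = np.arange(n)
            rel = pos[None, :] - pos[:, None]  # key minus query
            self._bucket_cache[n] = relative_position_bucket(
                rel, self.config.rel_pos_buckets, self.config.rel_pos_max_distance
            )
        return self._bucket_cache[n]

    def forward(self, tokens: np.ndarray, valid: np.ndarray | None = None,
                train: bool = False,
                dropout_rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor]:
        """Batched forward pass.

        tokens: (B, N) integer array, padded with the pad index.
        valid:  (B, N) boolean array marking real positions; defaults to all.
        Returns (hidden, log_dists) tensors of shape (B, N, d) and (B, N, V).
        """
        cfg = self.config
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim != 2:
            raise ValueError("tokens must be (batch, length)")
        b, n = tokens.shape
        if n > cfg.max_length:
            raise ValueError(f"input length {n} exceeds max_length {cfg.max_length}")
        if tokens.max() >= cfg.vocab_size or tokens.min() < 0:
            raise ValueError("token index out of vocabulary range")
        if valid is None:
            valid = np.ones((b, n), dtype=bool)

        h = self.embedding[tokens]  # (B, N, d) via gather
        nh, dh = cfg.num_heads, cfg.hidden_dim // cfg.num_heads

        if cfg.num_layers > 0:
            bias = self.rel_bias[self._buckets(n)]  # (N, N, nh)
            bias = bias.transpose(2, 0, 1).reshape(1, nh, n, n)
            key_mask = np.where(valid, 0.0, _NEG_INF).reshape(b, 1, 1, n)
            mask_t = constant(key_mask)

        drop = cfg.dropout if train else 0.0

        def _dropout(x: Tensor) -> Tensor:
            if drop <= 0.0:
                return x
            if dropout_rng is None:
                raise ValueError("dropout requires a generator in train mode")
            keep = (dropout_rng.random(x.shape) >= drop) / (1.0 - drop)
            return x * constant(keep)

        for layer in self.layers:
            x = _rms_norm(h, layer["attn_norm"])
            q = (x @ layer["wq"]).reshape(b, n, nh, dh).transpose(0, 2, 1, 3)
            k = (x @ layer["wk"]).reshape(b, n, nh, dh).transpose(0, 2, 1, 3)
            v = (x @ layer["wv"]).reshape(b, n, nh, dh).transpose(0, 2, 1, 3)
            scores = q @ k.transpose(0, 1, 3, 2) * dh**-0.5 + bias + mask_t
            attn = scores.softmax(axis=-1)
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, cfg.hidden_dim)
            h = h + _dropout(ctx @ layer["wo"])
            x = _rms_norm(h, layer["ffn_norm"])
            h = h + _dropout((x @ layer["wi"]).relu() @ layer["wf"])

        if self.final_norm is not None:
            h = _rms_norm(h, self.final_norm)
        logits = h @ self.embedding.transpose()  # tied output head
        return h, logits.log_softmax(axis=-1)

    def encode(self, ts: TokenSequence) -> StudentOutput:
        """Deterministic single-sequence forward pass (eval mode)."""
        tokens = np.array([ts.tokens], dtype=np.int64)
        hidden, log_dists = self.forward(tokens, train=False)
        lp = log_dists.data[0]
        return StudentOutput(hidden=hidden.data[0], dists=np.exp(lp), log_dists=lp)


def count_parameters(config: StudentConfig) -> int:
    """Exact trainable-scalar count implied by the architecture."""
    d, dff, v = config.hidden_dim, config.feedforward_dim, config.vocab_size
    per_layer = 4 * d * d + 2 * d * dff + 2 * d  # attn + ffn + two norm gains
    total = v * d + config.num_layers * per_layer
    if config.num_layers > 0:
        total += d + config.rel_pos_buckets * config.num_heads
    return total


# -- checkpointing --------------------------------------------------------------


def save_checkpoint(path, model: StudentModel, extra: dict | None = None) -> None:
    """Single-file container: config, parameters, vocabulary fingerprint."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {
        "config": asdict(model.config),
        "vocab_fingerprint": model.vocab.fingerprint(),
        "vocab_tokens": list(model.vocab.tokens),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    for key, val in (extra or {}).items():
        if isinstance(val, dict):
            arrays[f"extra_json_{key}"] = np.frombuffer(
                json.dumps(val).encode(), dtype=np.uint8)
        else:
            arrays[f"extra_arr_{key}"] = np.asarray(val)
    np.savez(path, **arrays)


def load_checkpoint(path, vocab: Vocabulary | None = None
                    ) -> tuple[StudentModel, dict]:
    """Load a checkpoint; refuses to load under a mismatched vocabulary."""
    vocab = vocab or Vocabulary()
    p = str(path)
    if not p.endswith(".npz"):
        p += ".npz"
    with np.load(p, allow_pickle=False) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        if meta["vocab_fingerprint"] != vocab.fingerprint():
            raise ValueError(
                "checkpoint vocabulary does not match the supplied vocabulary"
            )
        config = StudentConfig(**meta["config"])
        model = StudentModel(config, vocab=vocab, seed=0)
        for i, param in enumerate(model.parameters()):
            param.data = np.asarray(zf[f"param_{i}"], dtype=np.float64).copy()
        extra: dict = {}
        for key in zf.files:
            if key.startswith("extra_json_"):
                extra[key[len("extra_json_"):]] = json.loads(bytes(zf[key]).decode())
            elif key.startswith("extra_arr_"):
                extra[key[len("extra_arr_"):]] = np.asarray(zf[key])
    return model, extra
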