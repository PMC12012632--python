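"""Decoder-only transformer over state tokens, from scratch on numpy.

Architecture: token embedding plus fixed sinusoidal positional encoding,

    PE(k, 2i)   = sin(k / 10000^(2i/d)),
    PE(k, 2i+1) = cos(k / 10000^(2i/d)),

followed by ``n_blocks`` residual blocks of masked multi-head self-attention
(keys/queries/values K = X W_k, Q = X W_q, V = X W_v; scores Q K^T / sqrt(d_h)
with a strictly causal mask) and a position-wise feed-forward layer, a final
layer norm, and a linear head whose softmax yields the next-token
distribution.  Training minimizes the autoregressive cross-entropy
L = -(1/T) sum_t log p(O(t+1) | O(<=t)) with Adam on random windows sampled
from the training segments.

The attention-ablated variant (``attention_enabled=False``) drops the
attention sublayer while keeping norms and feed-forward layers, which removes
every cross-token communication path: logits at position t then depend on
token t alone.

Forward and backward passes are hand-written; a finite-difference gradient
check lives in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    PreconditionError,
    TrainingDivergedError,
    UnsupportedOperationError,
)
from .nn import Adam, clip_gradients, cross_entropy, glorot, layer_norm, \
    layer_norm_backward, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "GPTConfig",
    "GPTModel",
    "AttentionMap",
    "positional_encoding",
    "masked_attention",
    "train",
    "attention_scores",
    "ablate_attention",
]

NEG_INF = -1e9


@dataclass(frozen=True)
class GPTConfig:
    """Hyperparameters of the decoder-only transformer."""

    vocab_size: int
    embed_dim: int = 32          # d
    n_heads: int = 4             # N_h
    n_blocks: int = 2            # N_b
    block_size: int = 128        # context length l
    dropout: float = 0.0
    epochs: int = 2000           # optimization steps on sampled windows
    learning_rate: float = 3e-4
    batch_size: int = 64
    seed: int = 0
    attention_enabled: bool = True
    norm_placement: str = "pre"  # "pre" or "post" residual norm
    head_scale: str = "per_head"  # "per_head": sqrt(d/N_h); "embed": sqrt(d)
    grad_clip: float = 1.0
    val_interval: int = 25

    def __post_init__(self):
        if self.vocab_size < 2:
            raise ConfigurationError("vocab_size must be >= 2")
        if self.embed_dim % self.n_heads != 0:
            raise ConfigurationError("embed_dim must be divisible by n_heads")
        if self.block_size < 2:
            raise ConfigurationError("block_size must be >= 2")
        if self.norm_placement not in ("pre", "post"):
            raise ConfigurationError("norm_placement must be 'pre' or 'post'")
        if self.head_scale not in ("per_head", "embed"):
            raise ConfigurationError("head_scale must be 'per_head' or 'embed'")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def attn_scale(self) -> float:
        d = self.head_dim if self.head_scale == "per_head" else self.embed_dim
        return float(np.sqrt(d))


@dataclass
class AttentionMap:
    """Causal-masked attention scores averaged over heads and chunks."""

    scores: np.ndarray  # [l, l], zero above the diagonal
    n_heads: int
    n_chunks: int


def masked_attention(
    X_f: np.ndarray,
    Wq: np.ndarray,
    Wk: np.ndarray,
    Wv: np.ndarray,
    n_heads: int = 1,
    head_scale: str = "per_head",
) -> tuple[np.ndarray, AttentionMap]:
    """Single masked multi-head self-attention application.

    K = X_f W_k, Q = X_f W_q, V = X_f W_v; scores Q K^T / sqrt(d_h) with a
    strictly causal (lower-triangular) mask; per-head softmax-weighted sums
    of V are concatenated.  Returns the output and the raw pre-softmax
    scores (masked entries zeroed) averaged over heads.
    """
    X_f = np.asarray(X_f, dtype=np.float64)
    L, d = X_f.shape
    if d % n_heads != 0:
        raise ConfigurationError("embedding dim not divisible by n_heads")
    dh = d // n_heads
    scale = np.sqrt(dh if head_scale == "per_head" else d)
    q = (X_f @ Wq).reshape(L, n_heads, dh).transpose(1, 0, 2)
    k = (X_f @ Wk).reshape(L, n_heads, dh).transpose(1, 0, 2)
    v = (X_f @ Wv).reshape(L, n_heads, dh).transpose(1, 0, 2)
    S = q @ k.transpose(0, 2, 1) / scale
    mask = np.triu(np.ones((L, L), dtype=bool), k=1)
    S_masked = np.where(mask, NEG_INF, S)
    P = softmax(S_masked, axis=-1)
    out = (P @ v).transpose(1, 0, 2).reshape(L, d)
    scores = np.where(mask, 0.0, S).mean(axis=0)
    return out, AttentionMap(scores, n_heads=n_heads, n_chunks=1)


def positional_encoding(l: int, d: int) -> np.ndarray:
    """Sinusoidal positional-encoding table of shape [l, d] (d even)."""
    if d % 2 != 0:
        raise PreconditionError("embedding dimension must be even")
    k = np.arange(l)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = k / np.power(10000.0, 2.0 * i / d)
    pe = np.empty((l, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _init_params(cfg: GPTConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    d, v = cfg.embed_dim, cfg.vocab_size
    p: dict[str, np.ndarray] = {
        "tok_emb": 0.02 * rng.standard_normal((v, d)),
        "lnf_g": np.ones(d),
        "lnf_b": np.zeros(d),
        "head_W": glorot(rng, d, v),
        "head_b": np.zeros(v),
    }
    for b in range(cfg.n_blocks):
        if cfg.attention_enabled:
            p[f"b{b}.ln1_g"] = np.ones(d)
            p[f"b{b}.ln1_b"] = np.zeros(d)
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                p[f"b{b}.{nm}"] = glorot(rng, d, d)
            for nm in ("bq", "bk", "bv", "bo"):
                p[f"b{b}.{nm}"] = np.zeros(d)
        p[f"b{b}.ln2_g"] = np.ones(d)
        p[f"b{b}.ln2_b"] = np.zeros(d)
        p[f"b{b}.W1"] = glorot(rng, d, 4 * d)
        p[f"b{b}.b1"] = np.zeros(4 * d)
        p[f"b{b}.W2"] = glorot(rng, 4 * d, d)
        p[f"b{b}.b2"] = np.zeros(d)
    return p


class GPTModel:
    """A trained (or trainable) decoder-only transformer over state tokens.

    Exposes the shared sequence-model contract: ``forward`` (per-position
    next-token distributions), ``next_token_probs``, and ``loss``.
    """

    kind = "gpt"

    def __init__(self, config: GPTConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else _init_params(config)
        self.pe = positional_encoding(config.block_size, config.embed_dim)
        self.loss_history: dict[str, list] = {"train": [], "val": []}

    @property
    def vocab_size(self) -> int:
        return self.config.vocab_size

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------

    def _forward(self, X: np.ndarray, collect_scores: bool = False):
        """Forward pass on integer windows X [B, L].  Returns (logits, cache)."""
        cfg = self.config
        p = self.params
        B, L = X.shape
        if L > cfg.block_size:
            raise PreconditionError("window longer than block_size")
        if X.min() < 0 or X.max() >= cfg.vocab_size:
            raise PreconditionError("token outside vocabulary")
        h = p["tok_emb"][X] + self.pe[:L]
        cache: dict = {"X": X, "blocks": [], "scores": []}
        H, dh = cfg.n_heads, cfg.head_dim
        mask = np.triu(np.ones((L, L), dtype=bool), k=1)
        for b in range(cfg.n_blocks):
            blk: dict = {}
            if cfg.attention_enabled:
                if cfg.norm_placement == "pre":
                    a, blk["ln1"] = layer_norm(h, p[f"b{b}.ln1_g"], p[f"b{b}.ln1_b"])
                else:
                    a = h
                q = a @ p[f"b{b}.Wq"] + p[f"b{b}.bq"]
                kk = a @ p[f"b{b}.Wk"] + p[f"b{b}.bk"]
                v = a @ p[f"b{b}.Wv"] + p[f"b{b}.bv"]
                # [B, H, L, dh]
                qh = q.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
                kh = kk.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
                vh = v.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
                S = qh @ kh.transpose(0, 1, 3, 2) / cfg.attn_scale
                S = np.where(mask, NEG_INF, S)
                P = softmax(S, axis=-1)
                if collect_scores:
                    cache["scores"].append(np.where(mask, 0.0, S))
                o = (P @ vh).transpose(0, 2, 1, 3).reshape(B, L, cfg.embed_dim)
                attn_out = o @ p[f"b{b}.Wo"] + p[f"b{b}.bo"]
                blk.update(a=a, qh=qh, kh=kh, vh=vh, P=P, o=o, h_in=h)
                h = h + attn_out
                if cfg.norm_placement == "post":
                    h, blk["ln1"] = layer_norm(h, p[f"b{b}.ln1_g"], p[f"b{b}.ln1_b"])
            if cfg.norm_placement == "pre":
                a2, blk["ln2"] = layer_norm(h, p[f"b{b}.ln2_g"], p[f"b{b}.ln2_b"])
            else:
                a2 = h
            z1 = a2 @ p[f"b{b}.W1"] + p[f"b{b}.b1"]
            r1 = np.maximum(z1, 0.0)
            ffn_out = r1 @ p[f"b{b}.W2"] + p[f"b{b}.b2"]
            blk.update(a2=a2, r1=r1, h_mid=h)
            h = h + ffn_out
            if cfg.norm_placement == "post":
                h, blk["ln2"] = layer_norm(h, p[f"b{b}.ln2_g"], p[f"b{b}.ln2_b"])
            cache["blocks"].append(blk)
        g, cache["lnf"] = layer_norm(h, p["lnf_g"], p["lnf_b"])
        cache["g"] = g
        logits = g @ p["head_W"] + p["head_b"]
        return logits, cache

    def _backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        B, L, _ = dlogits.shape
        H, dh = cfg.n_heads, cfg.head_dim
        grads: dict[str, np.ndarray] = {}
        g = cache["g"]
        grads["head_W"] = g.reshape(-1, cfg.embed_dim).T @ dlogits.reshape(-1, cfg.vocab_size)
        grads["head_b"] = dlogits.sum(axis=(0, 1))
        dg = dlogits @ p["head_W"].T
        dh_, grads["lnf_g"], grads["lnf_b"] = layer_norm_backward(dg, cache["lnf"])
        for b in range(cfg.n_blocks - 1, -1, -1):
            blk = cache["blocks"][b]
            if cfg.norm_placement == "post":
                dh_, grads[f"b{b}.ln2_g"], grads[f"b{b}.ln2_b"] = layer_norm_backward(
                    dh_, blk["ln2"]
                )
            # FFN branch
            dffn = dh_
            dr1 = dffn @ p[f"b{b}.W2"].T
            r1 = blk["r1"]
            grads[f"b{b}.W2"] = r1.reshape(-1, 4 * cfg.embed_dim).T @ dffn.reshape(
                -1, cfg.embed_dim
            )
            grads[f"b{b}.b2"] = dffn.sum(axis=(0, 1))
            dz1 = dr1 * (r1 > 0)
            a2 = blk["a2"]
            grads[f"b{b}.W1"] = a2.reshape(-1, cfg.embed_dim).T @ dz1.reshape(
                -1, 4 * cfg.embed_dim
            )
            grads[f"b{b}.b1"] = dz1.sum(axis=(0, 1))
            da2 = dz1 @ p[f"b{b}.W1"].T
            if cfg.norm_placement == "pre":
                dmid, grads[f"b{b}.ln2_g"], grads[f"b{b}.ln2_b"] = layer_norm_backward(
                    da2, blk["ln2"]
                )
                dh_ = dh_ + dmid
            else:
                dh_ = dh_ + da2
            if not cfg.attention_enabled:
                continue
            # attention branch
            if cfg.norm_placement == "post":
                dh_, grads[f"b{b}.ln1_g"], grads[f"b{b}.ln1_b"] = layer_norm_backward(
                    dh_, blk["ln1"]
                )
            dattn = dh_
            o = blk["o"]
            grads[f"b{b}.Wo"] = o.reshape(-1, cfg.embed_dim).T @ dattn.reshape(
                -1, cfg.embed_dim
            )
            grads[f"b{b}.bo"] = dattn.sum(axis=(0, 1))
            do = (dattn @ p[f"b{b}.Wo"].T).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
            P, qh, kh, vh = blk["P"], blk["qh"], blk["kh"], blk["vh"]
            dP = do @ vh.transpose(0, 1, 3, 2)
            dvh = P.transpose(0, 1, 3, 2) @ do
            dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
            dS /= cfg.attn_scale
            dqh = dS @ kh
            dkh = dS.transpose(0, 1, 3, 2) @ qh
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, L, cfg.embed_dim)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, L, cfg.embed_dim)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, L, cfg.embed_dim)
            a = blk["a"]
            aT = a.reshape(-1, cfg.embed_dim).T
            grads[f"b{b}.Wq"] = aT @ dq.reshape(-1, cfg.embed_dim)
            grads[f"b{b}.Wk"] = aT @ dk.reshape(-1, cfg.embed_dim)
            grads[f"b{b}.Wv"] = aT @ dv.reshape(-1, cfg.embed_dim)
            grads[f"b{b}.bq"] = dq.sum(axis=(0, 1))
            grads[f"b{b}.bk"] = dk.sum(axis=(0, 1))
            grads[f"b{b}.bv"] = dv.sum(axis=(0, 1))
            da = (
                dq @ p[f"b{b}.Wq"].T
                + dk @ p[f"b{b}.Wk"].T
                + dv @ p[f"b{b}.Wv"].T
            )
            if cfg.norm_placement == "pre":
                din, grads[f"b{b}.ln1_g"], grads[f"b{b}.ln1_b"] = layer_norm_backward(
                    da, blk["ln1"]
                )
                dh_ = dh_ + din
            else:
                dh_ = dh_ + da
        # embedding gradient
        X = cache["X"]
        demb = np.zeros_like(p["tok_emb"])
        np.add.at(demb, X.ravel(), dh_.reshape(-1, cfg.embed_dim))
        grads["tok_emb"] = demb
        return grads

    # ------------------------------------------------------------------
    # public contract
    # ------------------------------------------------------------------

    def forward(self, tokens: Sequence[int] | np.ndarray) -> np.ndarray:
        """Next-token distribution at every position of a window; [L, vocab]."""
        X = np.asarray(tokens, dtype=np.int64)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        logits, _ = self._forward(X)
        probs = softmax(logits, axis=-1)
        return probs[0] if single else probs

    def next_token_probs(self, contexts: np.ndarray) -> np.ndarray:
        """Distribution after the last token of each context row; [B, vocab]."""
        logits, _ = self._forward(np.asarray(contexts, dtype=np.int64))
        return softmax(logits[:, -1, :], axis=-1)

    def loss(self, tokens: np.ndarray) -> float:
        """Mean autoregressive cross-entropy (nats/token) on one sequence."""
        toks = np.asarray(tokens, dtype=np.int64)
        if toks.size < 2:
            raise PreconditionError("need at least two tokens")
        total = 0.0
        count = 0
        w = self.config.block_size
        for start in range(0, toks.size - 1, w):
            window = toks[start : start + w + 1]
            if window.size < 2:
                break
            probs = self.forward(window[:-1])
            total += cross_entropy(probs, window[1:]) * (window.size - 1)
            count += window.size - 1
        return total / count


def _sample_windows(
    rng: np.random.Generator,
    segments: list[np.ndarray],
    n: int,
    width: int,
) -> np.ndarray:
    """Sample n windows of width+1 tokens, length-weighted across segments."""
    eligible = [s for s in segments if s.size >= width + 1]
    if not eligible:
        width = max(s.size for s in segments) - 1
        eligible = [s for s in segments if s.size >= width + 1]
    weights = np.array([s.size for s in eligible], dtype=float)
    weights /= weights.sum()
    out = np.empty((n, width + 1), dtype=np.int64)
    seg_idx = rng.choice(len(eligible), size=n, p=weights)
    for row, si in enumerate(seg_idx):
        s = eligible[si]
        start = rng.integers(0, s.size - width)
        out[row] = s[start : start + width + 1]
    return out


def train(
    segments: Sequence[np.ndarray] | np.ndarray,
    config: GPTConfig,
    val_segments: Sequence[np.ndarray] | None = None,
) -> GPTModel:
    """Train a decoder-only transformer on token segments.

    Each "epoch" is one Adam step on ``batch_size`` random windows of
    ``block_size + 1`` tokens (inputs are the first ``block_size`` tokens,
    targets the next-token shift).  Validation loss is recorded every
    ``val_interval`` epochs on windows from ``val_segments``.
    """
    if isinstance(segments, np.ndarray):
        segments = [segments]
    segments = [np.asarray(s, dtype=np.int64) for s in segments]
    if not segments or all(s.size < 2 for s in segments):
        raise PreconditionError("no trainable segments")
    present = np.unique(np.concatenate(segments))
    missing = set(range(config.vocab_size)) - set(present.tolist())
    if missing:
        logger.warning("states %s absent from training data", sorted(missing))

    model = GPTModel(config)
    rng = np.random.default_rng(config.seed + 7)
    opt = Adam(model.params, lr=config.learning_rate)
    width = min(config.block_size, max(s.size for s in segments) - 1)
    vals = None
    if val_segments is not None:
        vals = [np.asarray(s, dtype=np.int64) for s in val_segments
                if np.asarray(s).size >= 2]
        if not vals:
            vals = None

    for step in range(config.epochs):
        batch = _sample_windows(rng, segments, config.batch_size, width)
        X, Y = batch[:, :-1], batch[:, 1:]
        logits, cache = model._forward(X)
        probs = softmax(logits, axis=-1)
        loss = cross_entropy(probs, Y)
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"loss became non-finite at epoch {step}")
        model.loss_history["train"].append(loss)
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, Y[..., None],
            np.take_along_axis(dlogits, Y[..., None], axis=-1) - 1.0, axis=-1,
        )
        dlogits /= Y.size
        grads = model._backward(cache, dlogits)
        clip_gradients(grads, config.grad_clip)
        opt.step(grads)
        if vals is not None and (
            step % config.val_interval == 0 or step == config.epochs - 1
        ):
            vb = _sample_windows(rng, vals, min(32, config.batch_size), width)
            vprobs = softmax(model._forward(vb[:, :-1])[0], axis=-1)
            model.loss_history["val"].append(
                (step, cross_entropy(vprobs, vb[:, 1:]))
            )
    return model


def attention_scores(
    model: GPTModel, chunks: Sequence[np.ndarray], block: int | None = None
) -> AttentionMap:
    """Mean pre-softmax attention scores over heads x chunks (masked = 0).

    ``block=None`` averages over all transformer blocks as well.
    """
    if not model.config.attention_enabled:
        raise UnsupportedOperationError(
            "attention scores are undefined for an attention-ablated model"
        )
    chunks = [np.asarray(c, dtype=np.int64) for c in chunks]
    if not chunks:
        raise PreconditionError("need at least one chunk")
    L = chunks[0].size
    if any(c.size != L for c in chunks):
        raise PreconditionError("all chunks must have equal length")
    acc = np.zeros((L, L))
    for c in chunks:
        _, cache = model._forward(c[None, :], collect_scores=True)
        per_block = cache["scores"] if block is None else [cache["scores"][block]]
        for S in per_block:
            acc += S[0].mean(axis=0)  # average heads
    acc /= len(chunks) * (model.config.n_blocks if block is None else 1)
    return AttentionMap(acc, n_heads=model.config.n_heads, n_chunks=len(chunks))


def ablate_attention(config: GPTConfig) -> GPTConfig:
    """Config for the attention-ablated control (same everything else)."""
    return replace(config, attention_enabled=False)
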