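"""Baseline sequence models: Markov state models and an LSTM.

The MSM branch covers estimation (sliding-window transition counts at a
chosen lag, optionally with reversible maximum-likelihood symmetrization),
lag selection by implied timescales t_i(tau) = -tau / ln lambda_i(tau),
Chapman-Kolmogorov validation (T(tau)^k vs T(k tau) with bootstrap bands),
and generative Markov-chain sampling.  Generated sequences carry
dt_per_frame = lag * source dt: an MSM at lag > 1 can only emit states at
its own temporal resolution.

The LSTM is a single-layer recurrent next-token model with the same
embedding dimension and training contract as the transformer, so every
downstream kinetics metric applies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .discretize import StateSequence
from .errors import (
    ConfigurationError,
    PreconditionError,
    TrainingDivergedError,
)
from .gpt import _sample_windows
from .nn import Adam, clip_gradients, cross_entropy, glorot, softmax

__all__ = [
    "MarkovModel",
    "ImpliedTimescales",
    "CKTestResult",
    "estimate_msm",
    "implied_timescales",
    "select_lag",
    "ck_test",
    "msm_generate",
    "LSTMConfig",
    "LSTMModel",
    "train_lstm",
]


# ---------------------------------------------------------------------------
# Markov state models
# ---------------------------------------------------------------------------


@dataclass
class MarkovModel:
    """MSM at a single lag time, restricted to its largest connected set."""

    lag: int
    count_matrix: np.ndarray        # [k, k] on the active set
    transition_matrix: np.ndarray   # row-stochastic on the active set
    active_states: np.ndarray       # original state labels of the active set
    dropped_states: np.ndarray
    eigenvalues: np.ndarray         # sorted by |lambda| descending
    reversible: bool
    dt_per_frame: float = 1.0

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        idx = np.argmax(vals.real)
        pi = np.abs(vecs[:, idx].real)
        return pi / pi.sum()


@dataclass
class ImpliedTimescales:
    """t_i(tau) = -tau / ln lambda_i(tau); NaN where undefined, with flags."""

    lags: np.ndarray
    timescales: np.ndarray        # [n_lags, n_ts]; NaN where undefined
    undefined: np.ndarray         # bool mask, True where lambda <= 0/complex
    infinite: np.ndarray          # bool mask, True where lambda >= 1


@dataclass
class CKTestResult:
    """T(tau)^k self-transition probabilities vs direct T(k tau) estimates."""

    lag: int
    multiples: np.ndarray
    states: np.ndarray
    predicted: np.ndarray   # [n_multiples, k]
    estimated: np.ndarray   # [n_multiples, k]
    band_lo: np.ndarray
    band_hi: np.ndarray


def _count_matrix(tokens: np.ndarray, n_states: int, lag: int) -> np.ndarray:
    if lag < 1:
        raise PreconditionError("lag must be >= 1")
    if tokens.size <= lag:
        raise PreconditionError("sequence shorter than the lag")
    C = np.zeros((n_states, n_states))
    np.add.at(C, (tokens[:-lag], tokens[lag:]), 1.0)
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected set with any counts."""
    n = C.shape[0]
    _, labels = connected_components(
        csr_matrix(C > 0), directed=True, connection="strong"
    )
    sizes = np.bincount(labels, weights=C.sum(axis=1) + C.sum(axis=0))
    return np.flatnonzero(labels == np.argmax(sizes))


def _reversible_mle(C: np.ndarray, n_iter: int = 200, tol: float = 1e-12):
    """Reversible transition-matrix MLE by iterative proportional fitting."""
    X = 0.5 * (C + C.T)
    X[X == 0] = 0.0
    c_i = C.sum(axis=1)
    for _ in range(n_iter):
        x_i = X.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = c_i[:, None] / x_i[:, None] + c_i[None, :] / x_i[None, :]
            X_new = np.where(C + C.T > 0, (C + C.T) / denom, 0.0)
        if np.abs(X_new - X).max() < tol:
            X = X_new
            break
        X = X_new
    T = X / X.sum(axis=1, keepdims=True)
    return T


def estimate_msm(
    seq: StateSequence | np.ndarray,
    lag: int,
    reversible: bool = False,
) -> MarkovModel:
    """Sliding-window count matrix and row-normalized transition matrix."""
    if isinstance(seq, StateSequence):
        tokens, n_states, dt = seq.tokens, seq.n_states, seq.dt_per_frame
    else:
        tokens = np.asarray(seq, dtype=np.int64)
        n_states, dt = int(tokens.max()) + 1, 1.0
    C_full = _count_matrix(tokens, n_states, lag)
    active = _largest_scc(C_full)
    if active.size == 0:
        raise PreconditionError("no connected states at this lag")
    dropped = np.setdiff1d(np.arange(n_states), active)
    C = C_full[np.ix_(active, active)]
    rows = C.sum(axis=1)
    if np.any(rows == 0):
        bad = active[np.flatnonzero(rows == 0)]
        raise PreconditionError(f"state(s) {bad.tolist()} have no outgoing counts")
    T = _reversible_mle(C) if reversible else C / rows[:, None]
    vals = np.linalg.eigvals(T)
    vals = vals[np.argsort(-np.abs(vals))]
    return MarkovModel(
        lag=lag,
        count_matrix=C,
        transition_matrix=T,
        active_states=active,
        dropped_states=dropped,
        eigenvalues=vals,
        reversible=reversible,
        dt_per_frame=dt,
    )


def implied_timescales(
    seq: StateSequence | np.ndarray,
    lags: Sequence[int],
    reversible: bool = False,
) -> ImpliedTimescales:
    """Relaxation timescales -tau/ln lambda_i(tau) for the non-unit spectrum."""
    lags = np.asarray(list(lags), dtype=np.int64)
    if lags.min(initial=1) < 1:
        raise PreconditionError("lags must be >= 1")
    models = [estimate_msm(seq, int(t), reversible=reversible) for t in lags]
    n_ts = max(m.n_states for m in models) - 1
    ts = np.full((len(lags), n_ts), np.nan)
    undef = np.zeros((len(lags), n_ts), dtype=bool)
    inf = np.zeros((len(lags), n_ts), dtype=bool)
    for r, (tau, m) in enumerate(zip(lags, models)):
        evs = m.eigenvalues[1:]  # drop the stationary eigenvalue
        for c, lam in enumerate(evs[:n_ts]):
            if abs(lam.imag) > 1e-10 or lam.real <= 0:
                undef[r, c] = True
            elif lam.real >= 1.0:
                inf[r, c] = True
            else:
                ts[r, c] = -tau / np.log(lam.real)
    return ImpliedTimescales(lags, ts, undef, inf)


def select_lag(
    seq: StateSequence | np.ndarray,
    lags: Sequence[int],
    rel_tol: float = 0.10,
) -> int:
    """Smallest lag whose slowest implied timescale changes by less than
    ``rel_tol`` when the lag doubles (the ITS-plateau heuristic)."""
    lags = sorted(int(t) for t in lags)
    its = implied_timescales(seq, lags)
    slowest = its.timescales[:, 0]
    lag_arr = np.asarray(lags)
    for r, tau in enumerate(lag_arr):
        doubled = np.flatnonzero(lag_arr >= 2 * tau)
        if doubled.size == 0 or not np.isfinite(slowest[r]):
            continue
        t2 = slowest[doubled[0]]
        if np.isfinite(t2) and abs(t2 - slowest[r]) <= rel_tol * abs(slowest[r]):
            return int(tau)
    return int(lag_arr[-1])


def ck_test(
    model: MarkovModel,
    seq: StateSequence | np.ndarray,
    k_multiples: Sequence[int] = (2, 3, 4),
    n_bootstrap: int = 50,
    n_blocks: int = 20,
    seed: int = 0,
) -> CKTestResult:
    """Chapman-Kolmogorov test on self-transition probabilities.

    Bootstrap bands come from block-resampling the trajectory (contiguous
    blocks preserve the short-time correlation structure).
    """
    tokens = seq.tokens if isinstance(seq, StateSequence) else np.asarray(seq)
    ks = np.asarray(sorted(set(int(k) for k in k_multiples)), dtype=np.int64)
    if tokens.size <= model.lag * ks.max():
        raise PreconditionError("sequence too short for the largest lag multiple")
    states = model.active_states
    idx_of = {s: i for i, s in enumerate(states)}
    predicted = np.empty((ks.size, states.size))
    estimated = np.empty_like(predicted)
    lo = np.empty_like(predicted)
    hi = np.empty_like(predicted)
    rng = np.random.default_rng(seed)
    blocks = np.array_split(tokens, n_blocks)
    for r, k in enumerate(ks):
        Tk = np.linalg.matrix_power(model.transition_matrix, int(k))
        predicted[r] = np.diag(Tk)
        direct = estimate_msm(
            StateSequence(tokens, int(tokens.max()) + 1), int(model.lag * k)
        )
        for c, s in enumerate(states):
            if s in direct.active_states:
                estimated[r, c] = direct.transition_matrix[
                    np.flatnonzero(direct.active_states == s)[0],
                    np.flatnonzero(direct.active_states == s)[0],
                ]
            else:
                estimated[r, c] = np.nan
        boots = np.full((n_bootstrap, states.size), np.nan)
        for b in range(n_bootstrap):
            sample = np.concatenate(
                [blocks[i] for i in rng.integers(0, len(blocks), len(blocks))]
            )
            C = _count_matrix(sample, int(tokens.max()) + 1, int(model.lag * k))
            rows = C.sum(axis=1)
            for c, s in enumerate(states):
                if rows[s] > 0:
                    boots[b, c] = C[s, s] / rows[s]
        lo[r] = np.nanpercentile(boots, 2.5, axis=0)
        hi[r] = np.nanpercentile(boots, 97.5, axis=0)
    return CKTestResult(model.lag, ks, states, predicted, estimated, lo, hi)


def msm_generate(
    model: MarkovModel,
    start: int,
    n: int,
    seed: int = 0,
) -> StateSequence:
    """Markov-chain sampling from the estimated transition matrix.

    The output timestep is the model lag: dt_per_frame = lag * source dt.
    """
    if start not in model.active_states:
        raise PreconditionError(f"start state {start} is not in the active set")
    idx = int(np.flatnonzero(model.active_states == start)[0])
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.transition_matrix, axis=1)
    out = np.empty(n, dtype=np.int64)
    for t in range(n):
        idx = int(np.searchsorted(cum[idx], rng.random() * cum[idx, -1]))
        idx = min(idx, model.n_states - 1)
        out[t] = model.active_states[idx]
    n_states = int(model.active_states.max()) + 1
    return StateSequence(
        out,
        n_states=n_states,
        dt_per_frame=model.dt_per_frame * model.lag,
        meta={"model": "msm", "lag": model.lag, "seed": seed},
    )


# ---------------------------------------------------------------------------
# LSTM baseline
# ---------------------------------------------------------------------------


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class LSTMConfig:
    """Single-layer LSTM with the same interface as the transformer config."""

    vocab_size: int
    embed_dim: int = 32
    hidden_dim: int = 32
    block_size: int = 128
    epochs: int = 2000
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    grad_clip: float = 1.0
    val_interval: int = 25

    def __post_init__(self):
        if self.vocab_size < 2:
            raise ConfigurationError("vocab_size must be >= 2")


class LSTMModel:
    """Recurrent next-token model sharing the sequence-model contract."""

    kind = "lstm"

    def __init__(self, config: LSTMConfig, params=None):
        self.config = config
        if params is None:
            rng = np.random.default_rng(config.seed)
            d, h, v = config.embed_dim, config.hidden_dim, config.vocab_size
            params = {
                "emb": 0.02 * rng.standard_normal((v, d)),
                "Wx": glorot(rng, d, 4 * h),
                "Wh": glorot(rng, h, 4 * h),
                "b": np.zeros(4 * h),
                "head_W": glorot(rng, h, v),
                "head_b": np.zeros(v),
            }
            # positive forget-gate bias: standard recipe for gradient flow
            params["b"][h : 2 * h] = 1.0
        self.params = params
        self.loss_history: dict[str, list] = {"train": [], "val": []}

    @property
    def vocab_size(self) -> int:
        return self.config.vocab_size

    def _forward(self, X: np.ndarray):
        p = self.params
        h_dim = self.config.hidden_dim
        B, L = X.shape
        emb = p["emb"][X]  # [B, L, d]
        h = np.zeros((B, h_dim))
        c = np.zeros((B, h_dim))
        hs = np.empty((B, L, h_dim))
        cache = {"X": X, "gates": [], "cs": [], "hs_prev": [], "cs_prev": []}
        for t in range(L):
            z = emb[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim :])
            cache["hs_prev"].append(h)
            cache["cs_prev"].append(c)
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache["gates"].append((i, f, g, o, tc))
            cache["cs"].append(c)
        logits = hs @ p["head_W"] + p["head_b"]
        cache["hs"] = hs
        cache["emb"] = emb
        return logits, cache

    def _backward(self, cache, dlogits):
        p = self.params
        h_dim = self.config.hidden_dim
        B, L, _ = dlogits.shape
        hs = cache["hs"]
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["head_W"] = hs.reshape(-1, h_dim).T @ dlogits.reshape(-1, self.config.vocab_size)
        grads["head_b"] = dlogits.sum(axis=(0, 1))
        dh_seq = dlogits @ p["head_W"].T
        dh_next = np.zeros((B, h_dim))
        dc_next = np.zeros((B, h_dim))
        demb = np.zeros_like(cache["emb"])
        for t in range(L - 1, -1, -1):
            i, f, g, o, tc = cache["gates"][t]
            c_prev = cache["cs_prev"][t]
            h_prev = cache["hs_prev"][t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += cache["emb"][:, t].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh_next = dz @ p["Wh"].T
            demb[:, t] = dz @ p["Wx"].T
        np.add.at(grads["emb"], cache["X"].ravel(), demb.reshape(-1, self.config.embed_dim))
        return grads

    # shared contract -----------------------------------------------------

    def forward(self, tokens):
        X = np.asarray(tokens, dtype=np.int64)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        logits, _ = self._forward(X)
        probs = softmax(logits, axis=-1)
        return probs[0] if single else probs

    def next_token_probs(self, contexts):
        logits, _ = self._forward(np.asarray(contexts, dtype=np.int64))
        return softmax(logits[:, -1, :], axis=-1)

    def loss(self, tokens):
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


def train_lstm(
    segments: Sequence[np.ndarray] | np.ndarray,
    config: LSTMConfig,
    val_segments: Sequence[np.ndarray] | None = None,
) -> LSTMModel:
    """Train the LSTM baseline with the same window-sampling scheme as the
    transformer."""
    if isinstance(segments, np.ndarray):
        segments = [segments]
    segments = [np.asarray(s, dtype=np.int64) for s in segments]
    if not segments or all(s.size < 2 for s in segments):
        raise PreconditionError("no trainable segments")
    model = LSTMModel(config)
    rng = np.random.default_rng(config.seed + 7)
    opt = Adam(model.params, lr=config.learning_rate)
    width = min(config.block_size, max(s.size for s in segments) - 1)
    vals = None
    if val_segments is not None:
        vals = [np.asarray(s, dtype=np.int64) for s in val_segments
                if np.asarray(s).size >= 2]
        vals = vals or None
    for step in range(config.epochs):
        batch = _sample_windows(rng, segments, config.batch_size, width)
        X, Y = batch[:, :-1], batch[:, 1:]
        logits, cache = model._forward(X)
        probs = softmax(logits, axis=-1)
        loss = cross_entropy(probs, Y)
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"LSTM loss non-finite at epoch {step}")
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
            model.loss_history["val"].append((step, cross_entropy(vprobs, vb[:, 1:])))
    return model
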