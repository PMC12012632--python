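"""Autoregressive multinomial sampling of future state tokens.

Each new token is drawn from the model's next-token distribution at the end
of the current context (temperature 1, i.e. the raw softmax), appended, and
the context window slid so it never exceeds the model's block size.  An
ensemble run samples one continuation per independently trained model, with
member seeds spawned deterministically from a master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .discretize import StateSequence
from .errors import PreconditionError

logger = logging.getLogger(__name__)

__all__ = ["GenerationSpec", "GeneratedEnsemble", "generate", "generate_batch",
           "generate_ensemble"]


@dataclass(frozen=True)
class GenerationSpec:
    """How many tokens to sample, from what prompt, with what seed."""

    n_tokens: int
    prompt: tuple[int, ...] = ()
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tokens < 1:
            raise PreconditionError("n_tokens must be >= 1")
        if len(self.prompt) < 1:
            raise PreconditionError("prompt must be non-empty")
        if self.temperature <= 0:
            raise PreconditionError("temperature must be > 0")


@dataclass
class GeneratedEnsemble:
    """Generated continuations from n_s independently trained models."""

    sequences: list[StateSequence]
    seeds: list[int]
    manifest: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self):
        return len(self.sequences)


def generate(
    model,
    spec: GenerationSpec,
    dt_per_frame: float = 1.0,
) -> StateSequence:
    """Sample ``spec.n_tokens`` future tokens from a trained sequence model.

    The returned sequence contains only the newly generated tokens (the
    prompt is excluded).  Prompts longer than the model's context are
    truncated to the trailing block.
    """
    block = model.config.block_size
    prompt = np.asarray(spec.prompt, dtype=np.int64)
    if prompt.max(initial=0) >= model.vocab_size:
        raise PreconditionError("prompt token outside the model vocabulary")
    if prompt.size > block:
        logger.warning(
            "prompt of %d tokens truncated to trailing %d", prompt.size, block
        )
        prompt = prompt[-block:]
    rng = np.random.default_rng(spec.seed)
    context = prompt.copy()
    out = np.empty(spec.n_tokens, dtype=np.int64)
    for t in range(spec.n_tokens):
        probs = model.next_token_probs(context[None, :])[0]
        if spec.temperature != 1.0:
            logp = np.log(np.clip(probs, 1e-12, None)) / spec.temperature
            probs = np.exp(logp - logp.max())
            probs /= probs.sum()
        # inverse-CDF multinomial draw
        tok = int(np.searchsorted(np.cumsum(probs), rng.random() * probs.sum()))
        tok = min(tok, model.vocab_size - 1)
        out[t] = tok
        context = np.append(context, tok)
        if context.size > block:
            context = context[-block:]
    return StateSequence(
        out,
        n_states=model.vocab_size,
        dt_per_frame=dt_per_frame,
        meta={"prompt_len": int(prompt.size), "seed": spec.seed, "model": model.kind},
    )


def generate_batch(
    model,
    prompts: np.ndarray,
    n_tokens: int,
    seed: int = 0,
    dt_per_frame: float = 1.0,
) -> list[StateSequence]:
    """Sample one continuation per prompt row, advancing all in lockstep.

    All prompts must share a length; the batched forward pass makes an
    r-fold ensemble of continuations from one model nearly as cheap as one.
    """
    prompts = np.asarray(prompts, dtype=np.int64)
    if prompts.ndim != 2 or prompts.shape[0] < 1:
        raise PreconditionError("prompts must be a non-empty [B, L] array")
    block = model.config.block_size
    if prompts.shape[1] > block:
        prompts = prompts[:, -block:]
    B = prompts.shape[0]
    rng = np.random.default_rng(seed)
    context = prompts.copy()
    out = np.empty((B, n_tokens), dtype=np.int64)
    for t in range(n_tokens):
        probs = model.next_token_probs(context)
        cum = np.cumsum(probs, axis=1)
        draws = rng.random(B) * cum[:, -1]
        toks = np.minimum(
            (cum < draws[:, None]).sum(axis=1), model.vocab_size - 1
        )
        out[:, t] = toks
        context = np.concatenate([context, toks[:, None]], axis=1)
        if context.shape[1] > block:
            context = context[:, -block:]
    return [
        StateSequence(out[b], n_states=model.vocab_size, dt_per_frame=dt_per_frame,
                      meta={"seed": seed, "batch_row": b, "model": model.kind})
        for b in range(B)
    ]


def generate_ensemble(
    models: Sequence,
    prompts: Sequence[Sequence[int]],
    n_tokens: int,
    master_seed: int = 0,
    dt_per_frame: float = 1.0,
) -> GeneratedEnsemble:
    """One generated continuation per (model, prompt) pair.

    Member seeds are spawned from ``master_seed`` with a SeedSequence, so the
    streams are independent but the whole ensemble is reproducible.
    """
    if len(models) != len(prompts):
        raise PreconditionError("need exactly one prompt per model")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master_seed).spawn(len(models))
    ]
    sequences = []
    for model, prompt, seed in zip(models, prompts, child_seeds):
        spec = GenerationSpec(n_tokens=n_tokens, prompt=tuple(int(t) for t in prompt),
                              seed=seed)
        sequences.append(generate(model, spec, dt_per_frame=dt_per_frame))
    manifest = {"master_seed": master_seed, "member_seeds": child_seeds,
                "n_tokens": n_tokens}
    return GeneratedEnsemble(sequences, child_seeds, manifest)
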