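"""Discretization of continuous CV trajectories into token sequences.

K-means cluster labels are arbitrary, so clusters are renumbered in
descending order of population (ties broken by ascending first-CV
coordinate of the center), which makes repeated runs comparable.  A
uniform-binning mode along a 1D CV is provided for free-energy
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .errors import ParseError, PreconditionError
from .features import CVTrajectory

__all__ = [
    "StateSequence",
    "SegmentPlan",
    "TrainingSegment",
    "kmeans_discretize",
    "bin_discretize",
    "segment",
    "write_state_sequence",
    "read_state_sequence",
]


@dataclass
class StateSequence:
    """Integer token sequence over a finite state vocabulary."""

    tokens: np.ndarray
    n_states: int
    dt_per_frame: float = 1.0
    label_map: np.ndarray | None = None  # [n_states, cv_dim] cluster centers
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if self.tokens.ndim != 1:
            raise PreconditionError("tokens must be one-dimensional")
        if self.tokens.size and (
            self.tokens.min() < 0 or self.tokens.max() >= self.n_states
        ):
            raise PreconditionError("token outside [0, n_states)")

    def __len__(self) -> int:
        return self.tokens.size

    def histogram(self) -> np.ndarray:
        return np.bincount(self.tokens, minlength=self.n_states)


@dataclass(frozen=True)
class SegmentPlan:
    """How to carve a sequence into training segments for the ensemble."""

    n_segments: int = 10
    segment_length: int | None = None  # None -> 60% of the sequence
    prompt_length: int = 64
    continuation_length: int | None = None  # None -> until sequence end
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise PreconditionError("n_segments must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise PreconditionError("split fractions must sum to 1")


@dataclass
class TrainingSegment:
    """One ensemble member's data: training tokens, prompt, held-out truth."""

    train_tokens: np.ndarray
    val_tokens: np.ndarray
    prompt: np.ndarray
    continuation: np.ndarray
    start: int


def _relabel_by_population(labels: np.ndarray, centers: np.ndarray):
    """Renumber clusters by descending population; ties by ascending first
    center coordinate.  Returns (new_labels, new_centers, old->new map)."""
    k = centers.shape[0]
    pops = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-pops[c], centers[c, 0]))
    remap = np.empty(k, dtype=np.int64)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[labels], centers[order], remap


def kmeans_discretize(
    cv: CVTrajectory | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> StateSequence:
    """K-means (squared-Euclidean) discretization of a CV trajectory."""
    if isinstance(cv, CVTrajectory):
        data = cv.values
        dt = cv.dt_per_frame
    else:
        data = np.asarray(cv, dtype=np.float64)
        if data.ndim == 1:
            data = data[:, None]
        dt = 1.0
    if k < 2:
        raise PreconditionError("k must be >= 2")
    if data.shape[0] < k:
        raise PreconditionError("need at least k frames")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**32))
    labels = km.fit_predict(data)
    tokens, centers, _ = _relabel_by_population(labels, km.cluster_centers_)
    return StateSequence(
        tokens,
        n_states=k,
        dt_per_frame=dt,
        label_map=centers,
        meta={"method": "kmeans", "k": k, "seed": seed, "inertia": float(km.inertia_)},
    )


def bin_discretize(
    series: np.ndarray, n_bins: int = 30, dt_per_frame: float = 1.0
) -> StateSequence:
    """Uniform binning of a 1D CV series (for 1D free-energy work).

    Empty bins keep their index so that token -> bin-center lookup stays
    linear in the CV.
    """
    series = np.asarray(series, dtype=np.float64).ravel()
    if n_bins < 2:
        raise PreconditionError("n_bins must be >= 2")
    edges = np.linspace(series.min(), series.max(), n_bins + 1)
    tokens = np.clip(np.digitize(series, edges[1:-1]), 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return StateSequence(
        tokens,
        n_states=n_bins,
        dt_per_frame=dt_per_frame,
        label_map=centers[:, None],
        meta={"method": "binning", "edges": edges},
    )


def segment(seq: StateSequence, plan: SegmentPlan) -> list[TrainingSegment]:
    """Sample ``n_segments`` training segments with seeded RNG.

    Each segment is split train/validation per ``plan.split`` (the test
    share is left for the held-out continuation that follows the segment in
    the source sequence).  The generation prompt is the trailing
    ``prompt_length`` block of the segment.
    """
    n = len(seq)
    seg_len = plan.segment_length or int(0.6 * n)
    if seg_len > n:
        raise PreconditionError(f"segment_length {seg_len} exceeds sequence {n}")
    if seg_len < 2 * plan.prompt_length:
        raise PreconditionError("segment too short for the requested prompt")
    rng = np.random.default_rng(plan.seed)
    # leave room for at least one continuation frame after each segment
    max_start = n - seg_len - 1
    if max_start < 0:
        raise PreconditionError("sequence too short for segment plan")
    starts = np.sort(rng.integers(0, max_start + 1, size=plan.n_segments))
    out = []
    train_frac = plan.split[0] / (plan.split[0] + plan.split[1])
    for s in starts:
        toks = seq.tokens[s : s + seg_len]
        n_train = int(round(train_frac * seg_len))
        cont_end = n if plan.continuation_length is None else min(
            n, s + seg_len + plan.continuation_length
        )
        out.append(
            TrainingSegment(
                train_tokens=toks[:n_train],
                val_tokens=toks[n_train:],
                prompt=toks[-plan.prompt_length :],
                continuation=seq.tokens[s + seg_len : cont_end],
                start=int(s),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Plain-text / NPY state-sequence files
# ---------------------------------------------------------------------------


def write_state_sequence(seq: StateSequence, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, seq.tokens)
        return
    with open(path, "w") as fh:
        fh.write(f"# n_states={seq.n_states} dt_per_frame={seq.dt_per_frame!r}\n")
        for t in seq.tokens:
            fh.write(f"{int(t)}\n")


def read_state_sequence(path: str | Path) -> StateSequence:
    path = Path(path)
    if path.suffix == ".npy":
        tokens = np.load(path)
        return StateSequence(tokens, n_states=int(tokens.max()) + 1)
    tokens = []
    n_states = None
    dt = 1.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].split():
                    if part.startswith("n_states="):
                        n_states = int(part.split("=")[1])
                    elif part.startswith("dt_per_frame="):
                        dt = float(part.split("=")[1])
                continue
            try:
                tokens.append(int(line))
            except ValueError:
                raise ParseError(f"non-integer token {line!r}", line=lineno)
    arr = np.asarray(tokens, dtype=np.int64)
    if n_states is None:
        n_states = int(arr.max()) + 1 if arr.size else 0
    return StateSequence(arr, n_states=n_states, dt_per_frame=dt)
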