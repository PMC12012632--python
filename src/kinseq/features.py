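"""Feature extraction and collective-variable learning.

Continuous trajectories are turned into feature matrices (pairwise
inter-particle distances, radius of gyration) and compressed into
low-dimensional collective variables (CVs) with an encoder-decoder
autoencoder.  Autoencoder quality is scored by the fraction of variation
explained,

    FVE = 1 - sum_i ||X(i) - Y(i)||^2 / sum_i ||X(i) - Xbar||^2,

where X is the input, Y the reconstruction and Xbar the feature-wise mean.
Features are z-scored before training and the FVE is reported on the
standardized scale, which makes the score independent of the raw feature
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    PreconditionError,
    TrainingDivergedError,
)
from .nn import Adam, glorot
from .simulate import Trajectory

__all__ = [
    "FeatureMatrix",
    "AutoencoderSpec",
    "CVTrajectory",
    "Autoencoder",
    "pairwise_distances",
    "arithmetic_selection",
    "radius_of_gyration",
    "fve_score",
    "train_autoencoder",
    "compute_cv",
]


@dataclass
class FeatureMatrix:
    """Frame-by-feature matrix with labels and provenance."""

    values: np.ndarray
    feature_names: list[str]
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise PreconditionError("feature values must be [n_frames, n_features]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training hyperparameters of the autoencoder.

    ``hidden_layers`` lists the encoder widths between input and latent;
    the decoder mirrors them.  Hidden layers use tanh; the latent and
    output layers are linear.
    """

    latent_dim: int = 2
    hidden_layers: tuple[int, ...] | None = None  # None -> [max(16, F), 16]
    activation: str = "tanh"
    epochs: int = 60
    learning_rate: float = 1e-3
    batch_size: int = 256
    seed: int = 0

    def resolve_hidden(self, n_features: int) -> tuple[int, ...]:
        if self.hidden_layers is not None:
            return tuple(self.hidden_layers)
        return (max(16, n_features), 16)


@dataclass
class CVTrajectory:
    """Per-frame collective-variable values from a trained encoder."""

    values: np.ndarray
    fve: float
    encoder_ref: dict = field(default_factory=dict)
    dt_per_frame: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]


def arithmetic_selection(n_particles: int, count: int = 8, step: int = 4) -> list[int]:
    """Indices in arithmetic progression (defaults pick 8 beads, step 4)."""
    sel = list(range(0, step * count, step))
    if sel[-1] >= n_particles:
        raise PreconditionError(
            f"selection 0:{step * count}:{step} exceeds {n_particles} particles"
        )
    return sel


def pairwise_distances(
    traj: Trajectory, selection: Sequence[int] | None = None
) -> FeatureMatrix:
    """Euclidean distances between all C(k, 2) pairs of selected particles.

    Pairs are ordered lexicographically by (i, j) index; 8 selected beads
    give 28 features, 20 give 190.
    """
    if selection is None:
        selection = list(range(traj.n_particles))
    sel = list(selection)
    if len(set(sel)) != len(sel):
        raise PreconditionError("selection contains duplicate indices")
    if any(i < 0 or i >= traj.n_particles for i in sel):
        raise PreconditionError("selection index out of range")
    if len(sel) < 2:
        raise PreconditionError("need at least two selected particles")
    pairs = list(combinations(range(len(sel)), 2))
    coords = traj.frames[:, sel, :]
    values = np.empty((traj.n_frames, len(pairs)))
    for k, (a, b) in enumerate(pairs):
        values[:, k] = np.linalg.norm(coords[:, a] - coords[:, b], axis=1)
    names = [f"d({sel[a]},{sel[b]})" for a, b in pairs]
    return FeatureMatrix(values, names, source={"selection": sel, "mode": "pairdist"})


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Equal-mass radius of gyration per frame."""
    if traj.n_particles < 1:
        raise PreconditionError("trajectory has no particles")
    cm = traj.frames.mean(axis=1, keepdims=True)
    return np.sqrt(((traj.frames - cm) ** 2).sum(axis=2).mean(axis=1))


def fve_score(X: np.ndarray, Y: np.ndarray) -> float:
    """Fraction of variation explained by a reconstruction Y of X."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise PreconditionError("X and Y must have the same shape")
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0.0:
        raise DegenerateInputError("X has zero total variance; FVE undefined")
    return 1.0 - float(((X - Y) ** 2).sum()) / total


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(float)),
}


class Autoencoder:
    """Symmetric MLP autoencoder trained by Adam on z-scored features.

    Layer widths are ``[F, *hidden, L, *reversed(hidden), F]`` with the
    activation on hidden layers only.  ``encode``/``decode`` operate on raw
    (unstandardized) feature values.
    """

    def __init__(self, n_features: int, spec: AutoencoderSpec):
        if not 1 <= spec.latent_dim:
            raise PreconditionError("latent_dim must be >= 1")
        if spec.latent_dim >= n_features:
            raise PreconditionError("latent_dim must be < n_features")
        if spec.activation not in _ACTIVATIONS:
            raise PreconditionError(f"unknown activation {spec.activation!r}")
        self.spec = spec
        self.n_features = n_features
        hidden = spec.resolve_hidden(n_features)
        self.widths = [n_features, *hidden, spec.latent_dim, *hidden[::-1], n_features]
        self.latent_index = len(hidden) + 1  # layer whose output is the latent code
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, np.ndarray] = {}
        for i, (a, b) in enumerate(zip(self.widths[:-1], self.widths[1:])):
            self.params[f"W{i}"] = glorot(rng, a, b)
            self.params[f"b{i}"] = np.zeros(b)
        self.mean_ = np.zeros(n_features)
        self.std_ = np.ones(n_features)
        self.history: dict[str, list[float]] = {"loss": [], "fve": []}
        self._act, self._dact = _ACTIVATIONS[spec.activation]

    @property
    def n_layers(self) -> int:
        return len(self.widths) - 1

    def _forward(self, x: np.ndarray, until: int | None = None):
        """Forward through layers [0, until); returns activations list."""
        until = self.n_layers if until is None else until
        acts = [x]
        h = x
        for i in range(until):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            # linear at the latent layer and the output layer
            if i == self.latent_index - 1 or i == self.n_layers - 1:
                h = z
            else:
                h = self._act(z)
            acts.append(h)
        return acts

    # -- public surface ----------------------------------------------------

    def encode(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_
        return self._forward(Xs, until=self.latent_index)[-1]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        h = np.asarray(Z, dtype=np.float64)
        for i in range(self.latent_index, self.n_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = z if i == self.n_layers - 1 else self._act(z)
        return h * self.std_ + self.mean_

    def reconstruct_standardized(self, Xs: np.ndarray) -> np.ndarray:
        return self._forward(Xs)[-1]

    def fve(self, X: np.ndarray) -> float:
        Xs = (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_
        return fve_score(Xs, self.reconstruct_standardized(Xs))

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray) -> "Autoencoder":
        spec = self.spec
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] <= spec.batch_size:
            raise PreconditionError("need n_frames > batch_size")
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        self.std_ = std
        Xs = (X - self.mean_) / self.std_

        rng = np.random.default_rng(spec.seed + 1)
        opt = Adam(self.params, lr=spec.learning_rate)
        n = Xs.shape[0]
        for epoch in range(spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n - spec.batch_size + 1, spec.batch_size):
                batch = Xs[order[start : start + spec.batch_size]]
                acts = self._forward(batch)
                out = acts[-1]
                diff = out - batch
                loss = float((diff**2).mean())
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"autoencoder loss became non-finite at epoch {epoch}"
                    )
                epoch_loss += loss
                n_batches += 1
                grads = self._backward(acts, 2.0 * diff / diff.size)
                opt.step(grads)
            self.history["loss"].append(epoch_loss / max(1, n_batches))
            self.history["fve"].append(
                fve_score(Xs, self.reconstruct_standardized(Xs))
            )
        return self

    def _backward(self, acts, dout):
        grads: dict[str, np.ndarray] = {}
        delta = dout
        for i in range(self.n_layers - 1, -1, -1):
            a_prev = acts[i]
            a_cur = acts[i + 1]
            if not (i == self.latent_index - 1 or i == self.n_layers - 1):
                delta = delta * self._dact(a_cur)
            grads[f"W{i}"] = a_prev.T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.params[f"W{i}"].T
        return grads


def train_autoencoder(
    features: FeatureMatrix | np.ndarray, spec: AutoencoderSpec
) -> Autoencoder:
    """Train an autoencoder on a feature matrix; returns the fitted model
    (encoder + decoder + training curve in ``model.history``)."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    model = Autoencoder(X.shape[1], spec)
    return model.fit(X)


def compute_cv(
    model: Autoencoder,
    features: FeatureMatrix | np.ndarray,
    dt_per_frame: float = 1.0,
) -> CVTrajectory:
    """Project features into the latent space of a trained autoencoder."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    return CVTrajectory(
        values=model.encode(X),
        fve=model.fve(X),
        encoder_ref={"spec": model.spec, "widths": model.widths},
        dt_per_frame=dt_per_frame,
    )
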