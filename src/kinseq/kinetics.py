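"""Kinetic and thermodynamic validation of state sequences.

The evaluation surface used to compare source dynamics against generated
ones: per-state occupancy probabilities, commit-time transition-count
curves, detailed-balance diagnostics, and 1D free-energy reconstruction
(F = -kT ln P).

Commit-time counting: the sequence is decomposed into maximal constant
runs; a transition i -> j is counted at commit time tau when a run of i is
immediately followed by a run of j and min(L_i, L_j) >= tau (the symmetric
dwell rule; the asymmetric pre-dwell rule is available via ``rule="pre"``).
Counts are therefore non-increasing in tau, and at tau = 1 they sum to the
total number of token changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np

from .discretize import StateSequence
from .errors import PreconditionError

__all__ = [
    "TransitionCountCurve",
    "StateProbabilityTable",
    "FreeEnergyProfile",
    "runs_of",
    "state_probabilities",
    "commit_time_counts",
    "ensemble_commit_curves",
    "detailed_balance_report",
    "free_energy_1d",
    "compare_curves",
]


@dataclass
class TransitionCountCurve:
    """Transition counts vs commit time for one ordered state pair."""

    pair: tuple[int, int]
    commit_times: np.ndarray          # in frames
    counts: np.ndarray                # ensemble mean
    stderr: np.ndarray                # standard error over members
    member_counts: np.ndarray         # [n_members, n_tau]
    n_frames: float                   # mean member sequence length
    dt_per_frame: float = 1.0
    rule: str = "min"

    @property
    def n_members(self) -> int:
        return self.member_counts.shape[0]

    def per_10k(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts and stderr rescaled to counts per 10^4 frames."""
        scale = 1.0e4 / self.n_frames
        return self.counts * scale, self.stderr * scale


@dataclass
class StateProbabilityTable:
    """Per-state occupancy probability, mean +/- stderr over an ensemble."""

    probabilities: np.ndarray
    stderr: np.ndarray
    n_states: int
    n_members: int

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {
            s: (float(self.probabilities[s]), float(self.stderr[s]))
            for s in range(self.n_states)
        }


@dataclass
class FreeEnergyProfile:
    """F = -kT ln P over CV bins, shifted so the minimum is zero."""

    bin_centers: np.ndarray
    free_energy: np.ndarray   # kT units; NaN in empty bins
    occupied: np.ndarray      # bool mask
    kT: float = 1.0


def runs_of(tokens: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs as (state, length) pairs."""
    tokens = np.asarray(tokens)
    if tokens.size == 0:
        return []
    change = np.flatnonzero(np.diff(tokens)) + 1
    bounds = np.concatenate([[0], change, [tokens.size]])
    return [
        (int(tokens[bounds[k]]), int(bounds[k + 1] - bounds[k]))
        for k in range(len(bounds) - 1)
    ]


def _as_sequences(seqs) -> list[StateSequence]:
    if isinstance(seqs, StateSequence):
        return [seqs]
    return list(seqs)


def state_probabilities(seqs) -> StateProbabilityTable:
    """Occupancy frequencies per sequence, then ensemble mean and stderr."""
    members = _as_sequences(seqs)
    if not members:
        raise PreconditionError("no sequences given")
    n_states = members[0].n_states
    if any(len(m) == 0 for m in members):
        raise PreconditionError("empty sequence")
    if any(m.n_states != n_states for m in members):
        raise PreconditionError("sequences do not share a vocabulary")
    freqs = np.stack([m.histogram() / len(m) for m in members])
    mean = freqs.mean(axis=0)
    if len(members) > 1:
        stderr = freqs.std(axis=0, ddof=1) / np.sqrt(len(members))
    else:
        stderr = np.zeros(n_states)
    return StateProbabilityTable(mean, stderr, n_states, len(members))


def commit_time_counts(
    seq: StateSequence | np.ndarray,
    pair: tuple[int, int],
    commit_grid: Sequence[int],
    rule: str = "min",
) -> np.ndarray:
    """Counts of i -> j transitions surviving each commit time in the grid."""
    i, j = pair
    tokens = seq.tokens if isinstance(seq, StateSequence) else np.asarray(seq)
    if i == j:
        raise PreconditionError("pair states must differ")
    grid = np.asarray(list(commit_grid), dtype=np.int64)
    if grid.min(initial=1) < 1:
        raise PreconditionError("commit times must be >= 1")
    if rule not in ("min", "pre"):
        raise PreconditionError("rule must be 'min' or 'pre'")
    runs = runs_of(tokens)
    dwells = []
    for k in range(len(runs) - 1):
        (s1, l1), (s2, l2) = runs[k], runs[k + 1]
        if s1 == i and s2 == j:
            dwells.append(min(l1, l2) if rule == "min" else l1)
    dwells = np.asarray(dwells, dtype=np.int64)
    return (dwells[:, None] >= grid[None, :]).sum(axis=0).astype(np.float64)


def default_commit_grid(seqs, tau_max: int | None = None) -> np.ndarray:
    """tau = 1..tau_max with tau_max defaulting to the 99th percentile of
    run lengths across the given sequences."""
    if tau_max is None:
        lengths = [
            l for m in _as_sequences(seqs) for (_s, l) in runs_of(m.tokens)
        ]
        tau_max = max(1, int(np.percentile(lengths, 99))) if lengths else 1
    return np.arange(1, tau_max + 1)


def ensemble_commit_curves(
    seqs,
    pairs: Sequence[tuple[int, int]] | None = None,
    commit_grid: Sequence[int] | None = None,
    rule: str = "min",
) -> dict[tuple[int, int], TransitionCountCurve]:
    """Commit-time curves for every ordered pair, with ensemble error bars."""
    members = _as_sequences(seqs)
    n_states = members[0].n_states
    if pairs is None:
        pairs = [(i, j) for i, j in permutations(range(n_states), 2)]
    grid = (
        np.asarray(list(commit_grid), dtype=np.int64)
        if commit_grid is not None
        else default_commit_grid(members)
    )
    n_frames = float(np.mean([len(m) for m in members]))
    out = {}
    for pair in pairs:
        mc = np.stack(
            [commit_time_counts(m, pair, grid, rule=rule) for m in members]
        )
        mean = mc.mean(axis=0)
        if len(members) > 1:
            stderr = mc.std(axis=0, ddof=1) / np.sqrt(len(members))
        else:
            stderr = np.sqrt(np.maximum(mean, 0.0))  # Poisson fallback
        out[pair] = TransitionCountCurve(
            pair=pair,
            commit_times=grid,
            counts=mean,
            stderr=stderr,
            member_counts=mc,
            n_frames=n_frames,
            dt_per_frame=members[0].dt_per_frame,
            rule=rule,
        )
    return out


@dataclass
class PairAsymmetry:
    """Forward/backward asymmetry of one unordered state pair."""

    pair: tuple[int, int]
    z_by_tau: np.ndarray
    max_z: float
    flagged: bool


def detailed_balance_report(
    curves: dict[tuple[int, int], TransitionCountCurve],
    z_threshold: float = 3.0,
) -> dict[tuple[int, int], PairAsymmetry]:
    """Forward-vs-backward transition asymmetry per unordered pair.

    Transition events are rare and approximately Poisson, so the asymmetry
    is scored with the pooled counting error: with total forward/backward
    counts F(tau), B(tau) summed over ensemble members,

        z(tau) = (F - B) / sqrt(F + B),

    the standard Skellam/Poisson z-score.  Pairs whose maximum |z| over the
    commit grid exceeds the threshold are flagged as violating detailed
    balance.  (A member-scatter standard error would report certainty from
    deterministic +-1 run-pairing artifacts even when the flux imbalance is
    a single event.)
    """
    seen = set()
    report = {}
    for (i, j) in list(curves.keys()):
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        fwd = curves.get(key)
        bwd = curves.get((key[1], key[0]))
        if fwd is None or bwd is None:
            raise PreconditionError(f"missing forward or backward curve for {key}")
        F = fwd.member_counts.sum(axis=0)
        B = bwd.member_counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(F - B) / np.sqrt(F + B)
        z[np.asarray(F + B) == 0] = 0.0  # no events, no asymmetry
        max_z = float(z.max(initial=0.0))
        report[key] = PairAsymmetry(
            pair=key, z_by_tau=z, max_z=max_z, flagged=max_z > z_threshold
        )
    return report


def free_energy_1d(
    series: np.ndarray | StateSequence,
    kT: float = 1.0,
    n_bins: int = 30,
    bin_centers: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """Histogram -> probability -> F = -kT ln P, shifted so min(F) = 0.

    Accepts either a continuous CV series (uniformly binned) or an already
    bin-discretized StateSequence whose label_map holds the bin centers.
    """
    if isinstance(series, StateSequence):
        counts = series.histogram().astype(float)
        centers = (
            series.label_map[:, 0]
            if series.label_map is not None
            else np.arange(series.n_states, dtype=float)
        )
    else:
        values = np.asarray(series, dtype=np.float64).ravel()
        if values.size == 0:
            raise PreconditionError("empty series")
        counts, edges = np.histogram(values, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = counts.astype(float)
    if bin_centers is not None:
        centers = np.asarray(bin_centers, dtype=float)
    occupied = counts > 0
    if not occupied.any():
        raise PreconditionError("no occupied bins")
    if occupied.sum() == 1:
        import warnings

        warnings.warn("all probability mass in a single bin; degenerate profile")
    p = counts / counts.sum()
    F = np.full_like(p, np.nan)
    F[occupied] = -kT * np.log(p[occupied])
    F -= np.nanmin(F)
    return FreeEnergyProfile(centers, F, occupied, kT)


@dataclass
class CurveAgreement:
    """compare_curves result: fraction of grid points within 3 pooled SE."""

    agreement: float
    max_z: float
    n_points: int


def compare_curves(
    actual: TransitionCountCurve,
    generated: TransitionCountCurve,
    z_threshold: float = 3.0,
) -> CurveAgreement:
    """Agreement between two commit-time curves on a shared grid.

    Both curves are rescaled to counts per 10^4 frames before comparison
    (generated sequences are usually shorter or longer than the source).
    """
    if actual.pair != generated.pair:
        raise PreconditionError("curves are for different pairs")
    if actual.commit_times.shape != generated.commit_times.shape or np.any(
        actual.commit_times != generated.commit_times
    ):
        raise PreconditionError("curves use different commit grids")
    a, sa = actual.per_10k()
    g, sg = generated.per_10k()
    pooled = np.sqrt(sa**2 + sg**2)
    diff = np.abs(a - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / pooled
    z[(diff == 0) & (pooled == 0)] = 0.0
    z[(diff > 0) & (pooled == 0)] = np.inf
    ok = z <= z_threshold
    return CurveAgreement(
        agreement=float(ok.mean()),
        max_z=float(z.max(initial=0.0)),
        n_points=int(z.size),
    )
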