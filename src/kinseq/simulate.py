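"""Overdamped Brownian-dynamics simulators.

Two families of systems are provided, both in reduced units (lengths in the
particle/bead diameter sigma, energies in kT, times in the Brownian time
tau_BD = sigma^2 * gamma / kT):

* a single particle in a 2D multi-well "toy" potential

      V_p(x, y) = W * (x^p + y^p) - sum_i G(x, x_i) * G(y, y_i)

  with p = 6 for the three-well landscape and p = 4 for the four-well one,
  and G the unnormalized Gaussian exp(-(u - u0)^2 / (2 sigma_G^2));

* a 2D worm-like bead chain with stiff harmonic bonds, a harmonic bending
  potential about theta0 = pi, Hertzian excluded volume between non-bonded
  beads, and an optional tangential self-propulsion force along every bond
  (propulsion = 0 recovers the passive, detailed-balance-obeying chain).

Integration is plain Euler-Maruyama,

    r <- r + (dt / gamma) * F + sqrt(2 kT dt / gamma) * eta,

with eta i.i.d. standard normal per component, so the discrete noise has
per-component variance 2 kT dt / gamma.  Noise is drawn chunk-wise from a
seeded :class:`numpy.random.Generator` outside the jitted kernels, which makes
trajectories bit-reproducible for a given (spec, integrator, seed) triple.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .errors import (
    ConfigurationError,
    IntegrationDivergedError,
    ParseError,
    PreconditionError,
)

__all__ = [
    "ToyPotentialSpec",
    "PolymerSpec",
    "IntegratorSpec",
    "Trajectory",
    "three_state_spec",
    "four_state_spec",
    "paper_polymer_spec",
    "toy_potential_energy",
    "toy_force",
    "polymer_potential_energy",
    "polymer_forces",
    "run_bd_toy",
    "run_bd_polymer",
    "straight_chain",
    "write_trajectory",
    "read_trajectory",
]

# Printed model constants for the two toy landscapes.
THREE_STATE_CENTERS = ((0.0, 0.0), (-1.5, -1.5), (1.5, 1.5))
FOUR_STATE_CENTERS = ((0.0, 0.0), (2.0, -1.0), (0.5, 2.0), (-0.5, -2.0), (-2.0, 1.0))
TOY_WELL_AMPLITUDE = 0.0001
TOY_GAUSSIAN_WIDTH = 0.8


# ---------------------------------------------------------------------------
# Specs and the Trajectory container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyPotentialSpec:
    """Multi-well 2D potential: confining power-law plus Gaussian wells."""

    kind: str = "three_state"
    well_amplitude: float = TOY_WELL_AMPLITUDE
    gaussian_width: float = TOY_GAUSSIAN_WIDTH
    well_centers: tuple[tuple[float, float], ...] = THREE_STATE_CENTERS

    def __post_init__(self):
        if self.kind not in ("three_state", "four_state"):
            raise ConfigurationError(f"unknown toy potential kind {self.kind!r}")
        n_expected = 3 if self.kind == "three_state" else 5
        if len(self.well_centers) != n_expected:
            raise ConfigurationError(
                f"{self.kind} potential needs {n_expected} Gaussian centers, "
                f"got {len(self.well_centers)}"
            )
        if self.well_amplitude < 0:
            raise ConfigurationError("well_amplitude must be >= 0")
        if self.gaussian_width <= 0:
            raise ConfigurationError("gaussian_width must be > 0")

    @property
    def confining_power(self) -> int:
        return 6 if self.kind == "three_state" else 4


def three_state_spec() -> ToyPotentialSpec:
    """The printed three-well landscape (W=1e-4, sigma_G=0.8)."""
    return ToyPotentialSpec("three_state")


def four_state_spec() -> ToyPotentialSpec:
    """The printed four-well landscape (five Gaussians, W=1e-4)."""
    return ToyPotentialSpec("four_state", well_centers=FOUR_STATE_CENTERS)


@dataclass(frozen=True)
class PolymerSpec:
    """2D worm-like bead chain with optional tangential self-propulsion."""

    n_beads: int = 32
    bead_diameter: float = 1.0
    rest_length: float = 0.5
    bond_k: float = 1.0e4
    bend_k: float = 45.0
    rest_angle: float = np.pi
    hertz_E: float = 1.0e4
    propulsion: float = 5.0
    dims: int = 2

    def __post_init__(self):
        if self.n_beads < 3:
            raise ConfigurationError("n_beads must be >= 3")
        if self.dims != 2:
            raise ConfigurationError("only 2D chains are supported")

    @property
    def is_passive(self) -> bool:
        return self.propulsion == 0.0


def paper_polymer_spec(propulsion: float = 5.0) -> PolymerSpec:
    """The 32-bead chain with the printed parameters; propulsion=0 is passive."""
    return PolymerSpec(propulsion=propulsion)


@dataclass(frozen=True)
class IntegratorSpec:
    """Euler-Maruyama integration parameters, times in tau_BD units."""

    dt: float
    n_steps: int
    save_stride: int = 1
    gamma: float = 1.0
    kT: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ConfigurationError("n_steps and save_stride must be >= 1")
        if self.gamma <= 0 or self.kT < 0:
            raise ConfigurationError("gamma must be > 0 and kT >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.save_stride + 1

    @property
    def noise_amplitude(self) -> float:
        return float(np.sqrt(2.0 * self.kT * self.dt / self.gamma))


@dataclass
class Trajectory:
    """Time-ordered coordinate frames [n_frames, n_particles, dims]."""

    frames: np.ndarray
    dt_per_frame: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise PreconditionError("frames must be [n_frames, n_particles, dims]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]

    @property
    def dims(self) -> int:
        return self.frames.shape[2]


# ---------------------------------------------------------------------------
# Toy potential: energy, force, dynamics
# ---------------------------------------------------------------------------


def _toy_centers(spec: ToyPotentialSpec) -> np.ndarray:
    return np.asarray(spec.well_centers, dtype=np.float64)


def toy_potential_energy(spec: ToyPotentialSpec, point: Sequence[float]) -> float:
    """V(x, y) = W (x^p + y^p) - sum_i G(x, x_i) G(y, y_i)."""
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise PreconditionError("point must be finite")
    p = spec.confining_power
    s2 = 2.0 * spec.gaussian_width**2
    v = spec.well_amplitude * (x**p + y**p)
    for cx, cy in spec.well_centers:
        v -= np.exp(-((x - cx) ** 2) / s2) * np.exp(-((y - cy) ** 2) / s2)
    return float(v)


def toy_force(spec: ToyPotentialSpec, point: Sequence[float]) -> np.ndarray:
    """Analytic -grad V for the toy potential."""
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise PreconditionError("point must be finite")
    p = spec.confining_power
    sg2 = spec.gaussian_width**2
    dvdx = spec.well_amplitude * p * x ** (p - 1)
    dvdy = spec.well_amplitude * p * y ** (p - 1)
    for cx, cy in spec.well_centers:
        gx = np.exp(-((x - cx) ** 2) / (2 * sg2))
        gy = np.exp(-((y - cy) ** 2) / (2 * sg2))
        # d/dx [-gx*gy] = (x-cx)/sg2 * gx * gy
        dvdx += (x - cx) / sg2 * gx * gy
        dvdy += (y - cy) / sg2 * gx * gy
    return np.array([-dvdx, -dvdy])


@njit(cache=True)
def _toy_chunk(pos, centers, W, p, sg2, mobility_dt, noise):
    """Advance `noise.shape[0]` Euler steps in place; return index of first
    non-finite step or -1."""
    n_steps = noise.shape[0]
    n_centers = centers.shape[0]
    x, y = pos[0], pos[1]
    for s in range(n_steps):
        dvdx = W * p * x ** (p - 1)
        dvdy = W * p * y ** (p - 1)
        for c in range(n_centers):
            dx = x - centers[c, 0]
            dy = y - centers[c, 1]
            g = np.exp(-(dx * dx + dy * dy) / (2.0 * sg2))
            dvdx += dx / sg2 * g
            dvdy += dy / sg2 * g
        x += -mobility_dt * dvdx + noise[s, 0]
        y += -mobility_dt * dvdy + noise[s, 1]
        if not (np.isfinite(x) and np.isfinite(y)):
            return s
    pos[0] = x
    pos[1] = y
    return -1


def run_bd_toy(
    spec: ToyPotentialSpec,
    integ: IntegratorSpec,
    x0: Sequence[float] | None = None,
) -> Trajectory:
    """Euler-Maruyama trajectory of a single particle in the toy potential.

    When ``x0`` is None the particle starts at a well center chosen uniformly
    with the integrator seed.
    """
    rng = np.random.default_rng(integ.seed)
    centers = _toy_centers(spec)
    if x0 is None:
        x0 = centers[rng.integers(len(centers))]
    pos = np.asarray(x0, dtype=np.float64).copy()
    if pos.shape != (2,) or not np.all(np.isfinite(pos)):
        raise PreconditionError("x0 must be a finite (x, y) point")

    n_frames = integ.n_frames
    frames = np.empty((n_frames, 1, 2))
    frames[0, 0] = pos
    amp = integ.noise_amplitude
    mobility_dt = integ.dt / integ.gamma
    stride = integ.save_stride
    p = float(spec.confining_power)
    sg2 = spec.gaussian_width**2

    # Draw noise in chunks of whole save intervals to bound memory.
    frames_per_chunk = max(1, 100_000 // stride)
    frame = 1
    step_base = 0
    while frame < n_frames:
        n_save = min(frames_per_chunk, n_frames - frame)
        noise = amp * rng.standard_normal((n_save * stride, 2))
        for b in range(n_save):
            bad = _toy_chunk(
                pos, centers, spec.well_amplitude, p, sg2, mobility_dt,
                noise[b * stride : (b + 1) * stride],
            )
            if bad >= 0:
                raise IntegrationDivergedError(step_base + b * stride + bad)
            frames[frame, 0] = pos
            frame += 1
        step_base += n_save * stride

    meta = {"system": spec.kind, "spec": spec, "integrator": integ, "seed": integ.seed}
    return Trajectory(frames, dt_per_frame=integ.dt * stride, meta=meta)


# ---------------------------------------------------------------------------
# Worm-like polymer chain
# ---------------------------------------------------------------------------


@njit(cache=True)
def _polymer_forces(r, forces, d0, k0, k_ang, theta0, E, sigma, f_m):
    """Total force on each bead: -grad(V_bond + V_bend + V_nb) + propulsion."""
    n = r.shape[0]
    forces[:] = 0.0

    # Harmonic bonds
    for i in range(n - 1):
        dx = r[i + 1, 0] - r[i, 0]
        dy = r[i + 1, 1] - r[i, 1]
        dist = np.sqrt(dx * dx + dy * dy)
        if dist > 0.0:
            f = k0 * (dist - d0) / dist
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i + 1, 0] -= f * dx
            forces[i + 1, 1] -= f * dy

    # Harmonic bending about theta0 (angle at bead i between the vectors to
    # its two neighbours; straight chain has theta = pi).
    for i in range(1, n - 1):
        ux = r[i - 1, 0] - r[i, 0]
        uy = r[i - 1, 1] - r[i, 1]
        vx = r[i + 1, 0] - r[i, 0]
        vy = r[i + 1, 1] - r[i, 1]
        nu = np.sqrt(ux * ux + uy * uy)
        nv = np.sqrt(vx * vx + vy * vy)
        if nu == 0.0 or nv == 0.0:
            continue
        cos_t = (ux * vx + uy * vy) / (nu * nv)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        # dV/dtheta / sin(theta); the theta -> theta0 = pi limit is -k_ang.
        if sin_t < 1.0e-8:
            if abs(theta0 - np.pi) < 1.0e-12:
                coeff = -k_ang
            else:
                coeff = k_ang * (theta - theta0) / 1.0e-8
        else:
            coeff = k_ang * (theta - theta0) / sin_t
        # d(cos theta)/du etc.
        dcdux = vx / (nu * nv) - cos_t * ux / (nu * nu)
        dcduy = vy / (nu * nv) - cos_t * uy / (nu * nu)
        dcdvx = ux / (nu * nv) - cos_t * vx / (nv * nv)
        dcdvy = uy / (nu * nv) - cos_t * vy / (nv * nv)
        # F = -dV/dr with dtheta/dr = -(1/sin) dcos/dr  =>  F = +coeff * dcos/dr
        fux = coeff * dcdux
        fuy = coeff * dcduy
        fvx = coeff * dcdvx
        fvy = coeff * dcdvy
        forces[i - 1, 0] += fux
        forces[i - 1, 1] += fuy
        forces[i + 1, 0] += fvx
        forces[i + 1, 1] += fvy
        forces[i, 0] -= fux + fvx
        forces[i, 1] -= fuy + fvy

    # Hertzian excluded volume between non-bonded bead pairs (|i-j| >= 2)
    sig2 = sigma * sigma
    for i in range(n):
        for j in range(i + 2, n):
            dx = r[i, 0] - r[j, 0]
            dy = r[i, 1] - r[j, 1]
            r2 = dx * dx + dy * dy
            if r2 < sig2 and r2 > 0.0:
                dist = np.sqrt(r2)
                overlap = 1.0 - dist / sigma
                f = 2.5 * E / sigma * overlap * np.sqrt(overlap) / dist
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[j, 0] -= f * dx
                forces[j, 1] -= f * dy

    # Tangential self-propulsion: f_m along each bond unit vector, split
    # equally between the two beads of the bond.
    if f_m != 0.0:
        for i in range(n - 1):
            dx = r[i + 1, 0] - r[i, 0]
            dy = r[i + 1, 1] - r[i, 1]
            dist = np.sqrt(dx * dx + dy * dy)
            if dist > 0.0:
                fx = 0.5 * f_m * dx / dist
                fy = 0.5 * f_m * dy / dist
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i + 1, 0] += fx
                forces[i + 1, 1] += fy


@njit(cache=True)
def _polymer_chunk(r, forces, noise, stride, mobility_dt, d0, k0, k_ang,
                   theta0, E, sigma, f_m, out_frames):
    """Advance out_frames.shape[0] save intervals of `stride` steps each."""
    n_save = out_frames.shape[0]
    n = r.shape[0]
    for b in range(n_save):
        for s in range(stride):
            _polymer_forces(r, forces, d0, k0, k_ang, theta0, E, sigma, f_m)
            idx = b * stride + s
            for i in range(n):
                r[i, 0] += mobility_dt * forces[i, 0] + noise[idx, i, 0]
                r[i, 1] += mobility_dt * forces[i, 1] + noise[idx, i, 1]
        ok = True
        for i in range(n):
            if not (np.isfinite(r[i, 0]) and np.isfinite(r[i, 1])):
                ok = False
        if not ok:
            return b * stride + stride - 1
        out_frames[b] = r
    return -1


def polymer_potential_energy(spec: PolymerSpec, r: np.ndarray) -> float:
    """Total conservative energy V_bond + V_bend + V_nb of a configuration."""
    r = np.asarray(r, dtype=np.float64)
    n = spec.n_beads
    v = 0.0
    for i in range(n - 1):
        d = np.linalg.norm(r[i + 1] - r[i])
        v += 0.5 * spec.bond_k * (d - spec.rest_length) ** 2
    for i in range(1, n - 1):
        u = r[i - 1] - r[i]
        w = r[i + 1] - r[i]
        cos_t = np.clip(np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)), -1, 1)
        theta = np.arccos(cos_t)
        v += 0.5 * spec.bend_k * (theta - spec.rest_angle) ** 2
    for i in range(n):
        for j in range(i + 2, n):
            d = np.linalg.norm(r[i] - r[j])
            if d < spec.bead_diameter:
                v += spec.hertz_E * (1 - d / spec.bead_diameter) ** 2.5
    return float(v)


def polymer_forces(spec: PolymerSpec, r: np.ndarray, include_propulsion=True) -> np.ndarray:
    """Per-bead forces; conservative part is the analytic -grad of the energy."""
    r = np.ascontiguousarray(r, dtype=np.float64)
    forces = np.zeros_like(r)
    f_m = spec.propulsion if include_propulsion else 0.0
    _polymer_forces(
        r, forces, spec.rest_length, spec.bond_k, spec.bend_k,
        spec.rest_angle, spec.hertz_E, spec.bead_diameter, f_m,
    )
    return forces


def straight_chain(spec: PolymerSpec) -> np.ndarray:
    """Straight chain along x with bond length = rest_length (default init)."""
    r = np.zeros((spec.n_beads, 2))
    r[:, 0] = np.arange(spec.n_beads) * spec.rest_length
    return r


def run_bd_polymer(
    spec: PolymerSpec,
    integ: IntegratorSpec,
    init: np.ndarray | None = None,
) -> Trajectory:
    """Euler-Maruyama trajectory of the (active) worm-like chain."""
    if init is None:
        init = straight_chain(spec)
    r = np.ascontiguousarray(init, dtype=np.float64).copy()
    if r.shape != (spec.n_beads, 2):
        raise PreconditionError(f"init must have shape ({spec.n_beads}, 2)")
    # no two beads may coincide
    from scipy.spatial.distance import pdist

    if np.min(pdist(r)) <= 0.0:
        raise PreconditionError("initial configuration has overlapping beads")

    rng = np.random.default_rng(integ.seed)
    n_frames = integ.n_frames
    frames = np.empty((n_frames, spec.n_beads, 2))
    frames[0] = r
    amp = integ.noise_amplitude
    mobility_dt = integ.dt / integ.gamma
    stride = integ.save_stride
    forces = np.zeros_like(r)

    frames_per_chunk = max(1, 20_000 // stride)
    frame = 1
    step_base = 0
    while frame < n_frames:
        n_save = min(frames_per_chunk, n_frames - frame)
        noise = amp * rng.standard_normal((n_save * stride, spec.n_beads, 2))
        bad = _polymer_chunk(
            r, forces, noise, stride, mobility_dt, spec.rest_length,
            spec.bond_k, spec.bend_k, spec.rest_angle, spec.hertz_E,
            spec.bead_diameter, spec.propulsion,
            frames[frame : frame + n_save],
        )
        if bad >= 0:
            raise IntegrationDivergedError(step_base + bad)
        frame += n_save
        step_base += n_save * stride

    meta = {
        "system": "polymer_active" if not spec.is_passive else "polymer_passive",
        "spec": spec,
        "integrator": integ,
        "seed": integ.seed,
    }
    return Trajectory(frames, dt_per_frame=integ.dt * stride, meta=meta)


# ---------------------------------------------------------------------------
# Trajectory I/O (NPY, CSV, XYZ)
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "npy"
    if fmt == "npy":
        np.save(path, traj.frames)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            cols = ["frame", "particle"] + ["xyz"[d] for d in range(traj.dims)]
            writer.writerow(cols)
            for t in range(traj.n_frames):
                for i in range(traj.n_particles):
                    writer.writerow(
                        [t, i] + [repr(float(v)) for v in traj.frames[t, i]]
                    )
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for t in range(traj.n_frames):
                fh.write(f"{traj.n_particles}\n")
                fh.write(f"frame {t}\n")
                for i in range(traj.n_particles):
                    coords = list(traj.frames[t, i]) + [0.0] * (3 - traj.dims)
                    fh.write("X " + " ".join(repr(float(c)) for c in coords) + "\n")
    else:
        raise ConfigurationError(f"unknown trajectory format {fmt!r}")


def read_trajectory(
    path: str | Path, format: str | None = None, dt_per_frame: float = 1.0,
    dims: int | None = None,
) -> Trajectory:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "npy"
    if fmt == "npy":
        frames = np.load(path)
        if frames.ndim == 2:  # [n_frames, dims] single particle
            frames = frames[:, None, :]
        return Trajectory(frames, dt_per_frame, meta={"source": str(path)})
    if fmt == "csv":
        rows = []
        with open(path) as fh:
            reader = csv.reader(fh)
            header = next(reader)
            ncoord = len(header) - 2
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                try:
                    rows.append([float(v) for v in row])
                except ValueError:
                    raise ParseError(f"non-numeric cell in row {row!r}", line=lineno)
                if len(row) != ncoord + 2:
                    raise ParseError("wrong number of columns", line=lineno)
        arr = np.asarray(rows)
        n_frames = int(arr[:, 0].max()) + 1
        n_particles = int(arr[:, 1].max()) + 1
        frames = np.full((n_frames, n_particles, ncoord), np.nan)
        frames[arr[:, 0].astype(int), arr[:, 1].astype(int)] = arr[:, 2:]
        if np.isnan(frames).any():
            raise ParseError("missing (frame, particle) entries")
        return Trajectory(frames, dt_per_frame, meta={"source": str(path)})
    if fmt == "xyz":
        frames = []
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        lineno = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError:
                raise ParseError("expected atom count", line=i + 1)
            if i + 2 + n > len(lines):
                raise ParseError(
                    f"frame declares {n} atoms but file ends early", line=i + 1
                )
            block = []
            for j in range(n):
                parts = lines[i + 2 + j].split()
                if len(parts) < 4:
                    raise ParseError("short XYZ atom line", line=i + 3 + j)
                try:
                    block.append([float(v) for v in parts[1:4]])
                except ValueError:
                    raise ParseError("non-numeric XYZ coordinate", line=i + 3 + j)
            frames.append(block)
            i += 2 + n
        arr = np.asarray(frames)
        if dims is not None:
            arr = arr[:, :, :dims]
        elif np.all(arr[:, :, 2] == 0.0):
            arr = arr[:, :, :2]
        return Trajectory(arr, dt_per_frame, meta={"source": str(path)})
    raise ConfigurationError(f"unknown trajectory format {fmt!r}")
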