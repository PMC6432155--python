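"""Brownian-dynamics simulation of a self-attractive pearl-necklace chain.

Reduced Lennard-Jones units throughout: bead mass m, diameter sigma and
attraction epsilon are all 1, so the time unit is tau = sqrt(m sigma^2 /
epsilon).  A chain of N beads (L* = N convention: one bead per sigma of
contour) is integrated with a Langevin thermostat at dimensionless
temperature T* = kB T / epsilon.

The thermostat friction follows the damp-time convention: the friction
force on each bead is -(m / damp) v, so ``damp`` is the velocity relaxation
time in tau.  The default integrator is BAOAB splitting of underdamped
Langevin dynamics, which reduces exactly to velocity Verlet when
``damp=None`` (the NVE limit) and remains stable with stiff bonds at
dt = 0.005 tau.  A position-only Euler-Maruyama integrator for the
overdamped limit is available via ``integrator="overdamped"`` (note its
mobility dt*damp/m requires a smaller time step when bonds are stiff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .mapping import BendingPotential

__all__ = [
    "Configuration",
    "ForceField",
    "EnergyTerms",
    "Trajectory",
    "SimulationUnstableError",
    "build_chain",
    "compute_forces",
    "run_bd",
    "radius_of_gyration",
]

_ANGLE_CODE = {"harmonic": _kernels.ANGLE_HARMONIC,
               "cosine": _kernels.ANGLE_COSINE,
               "stiff": _kernels.ANGLE_STIFF}

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class SimulationUnstableError(RuntimeError):
    """Raised when coordinates or energies blow up; carries the step index."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"simulation unstable at step {step}")


@dataclass
class Configuration:
    """Bead coordinates (N x 3) and optional velocities, open boundaries."""

    positions: np.ndarray
    velocities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.velocities is not None:
            self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            None if self.velocities is None else self.velocities.copy(),
        )


@dataclass(frozen=True)
class ForceField:
    """Bead-spring force field: stiff harmonic bonds, bending, LJ 12-6 pairs.

    The LJ energy is shifted to zero at the cutoff; ``lj_cutoff`` equal to
    2^(1/6) sigma gives the purely repulsive (WCA) athermal control.
    Directly bonded (1-2) pairs are excluded from the pair sum; 1-3 pairs
    interact.
    """

    bond_k: float = 1000.0
    bond_l0: float = 1.0
    angle: BendingPotential = field(default_factory=lambda: BendingPotential("harmonic", 0.0))
    lj_epsilon: float = 1.0
    lj_sigma: float = 1.0
    lj_cutoff: float = 2.5

    def __post_init__(self) -> None:
        for name in ("bond_k", "bond_l0", "lj_epsilon", "lj_sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.lj_cutoff < WCA_CUTOFF * self.lj_sigma:
            raise ValueError("lj_cutoff must be at least 2^(1/6) sigma")

    def repulsive_only(self) -> "ForceField":
        """WCA variant of this force field (cutoff at the LJ minimum)."""
        return replace(self, lj_cutoff=WCA_CUTOFF * self.lj_sigma)

    def _kernel_args(self) -> tuple:
        return (self.bond_k, self.bond_l0, self.angle.K_theta,
                _ANGLE_CODE[self.angle.kind], self.lj_epsilon,
                self.lj_sigma, self.lj_cutoff)


@dataclass(frozen=True)
class EnergyTerms:
    bond: float
    angle: float
    pair: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.pair


@dataclass
class Trajectory:
    """Frames at the thermo stride plus per-frame thermodynamic records.

    ``thermo`` maps column name to array: step, time, e_bond, e_angle,
    e_pair, ke, temp, rg; temperature is kinetic, (1/3N) sum m v^2.
    """

    frames: list
    times: list
    thermo: dict

    @property
    def final(self) -> Configuration:
        return self.frames[-1]


def build_chain(N: int, l0: float = 1.0, seed: Optional[int] = None,
                init: str = "straight") -> Configuration:
    """Initial self-avoiding conformation of an N-bead chain.

    ``init="straight"`` places beads along the x axis at spacing ``l0``;
    ``init="random_walk"`` grows a seeded freely jointed walk, rejecting
    steps that bring any bead pair closer than 0.9 sigma.
    """
    if N < 3:
        raise ValueError(f"need at least 3 beads for a chain, got {N}")
    if init == "straight":
        pos = np.zeros((N, 3))
        pos[:, 0] = np.arange(N) * l0
        return Configuration(pos)
    if init != "random_walk":
        raise ValueError(f"unknown init {init!r}")
    rng = np.random.default_rng(seed)
    pos = np.zeros((N, 3))
    i = 1
    while i < N:
        for _attempt in range(1000):
            v = rng.normal(size=3)
            step = l0 * v / np.linalg.norm(v)
            cand = pos[i - 1] + step
            d2 = np.sum((pos[:i - 1] - cand) ** 2, axis=1)
            if d2.size == 0 or d2.min() >= (0.9 * l0) ** 2:
                pos[i] = cand
                i += 1
                break
        else:  # dead end: back up one bead and retry
            i = max(1, i - 1)
    return Configuration(pos)


def compute_forces(config: Configuration, ff: ForceField):
    """Forces (-grad U) and the bond/angle/pair energy decomposition.

    Raises SimulationUnstableError when two interacting beads overlap to
    within 1e-6 sigma (singular LJ force).
    """
    forces = np.empty_like(config.positions)
    e_bond, e_angle, e_pair, singular = _kernels.compute_forces_kernel(
        config.positions, *ff._kernel_args(), forces)
    if singular:
        raise SimulationUnstableError(-1, "overlapping beads: singular pair force")
    return forces, EnergyTerms(bond=e_bond, angle=e_angle, pair=e_pair)


def radius_of_gyration(config: Configuration) -> float:
    """RMS bead distance from the centre of mass (equal masses)."""
    pos = config.positions
    d = pos - pos.mean(axis=0)
    return math.sqrt(float(np.mean(np.sum(d * d, axis=1))))


def _check_finite(pos: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(pos)) or np.max(np.abs(pos)) > 1e6:
        raise SimulationUnstableError(step)


def run_bd(
    config: Configuration,
    ff: ForceField,
    steps: int,
    dt: float = 0.005,
    damp: Optional[float] = 10.0,
    T_star: float = 1.0,
    seed: int = 0,
    thermo_every: int = 1000,
    integrator: str = "langevin",
) -> Trajectory:
    """Integrate Langevin dynamics for ``steps`` steps and record thermo/frames.

    ``damp`` is the velocity relaxation time m/gamma in tau (friction
    coefficient gamma = m/damp); ``damp=None`` switches the thermostat off
    (NVE, velocity Verlet).  Reproducible for a given ``seed``.  Frames and
    thermodynamic records are taken every ``thermo_every`` steps, including
    step 0 and the final step.  Raises SimulationUnstableError (with the
    offending step index) on numerical blow-up.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if thermo_every < 1:
        raise ValueError("thermo_every must be >= 1")
    if integrator not in ("langevin", "overdamped"):
        raise ValueError(f"unknown integrator {integrator!r}")
    if integrator == "overdamped" and damp is None:
        raise ValueError("overdamped integrator requires a finite damp")

    pos = np.ascontiguousarray(config.positions, dtype=np.float64).copy()
    n = pos.shape[0]
    rng = np.random.default_rng(seed)

    if integrator == "langevin":
        if config.velocities is not None:
            vel = config.velocities.copy()
        elif T_star > 0 and damp is not None:
            vel = rng.normal(0.0, math.sqrt(T_star), size=(n, 3))
        else:
            vel = np.zeros((n, 3))
        gamma = 0.0 if damp is None else 1.0 / damp
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(max(T_star, 0.0) * (1.0 - c1 * c1))
    else:
        vel = None
        zeta = 1.0 / damp  # friction coefficient m/damp, as in the thermostat

    kernel_args = ff._kernel_args()
    forces = np.empty_like(pos)
    e_bond, e_angle, e_pair, singular = _kernels.compute_forces_kernel(
        pos, *kernel_args, forces)
    if singular:
        raise SimulationUnstableError(0, "singular forces in the initial configuration")

    cols = ("step", "time", "e_bond", "e_angle", "e_pair", "ke", "temp", "rg")
    thermo = {c: [] for c in cols}
    frames: list = []
    times: list = []

    def record(step: int) -> None:
        ke = 0.0 if vel is None else 0.5 * float(np.sum(vel * vel))
        temp = 0.0 if vel is None else 2.0 * ke / (3.0 * n)
        conf = Configuration(pos.copy(), None if vel is None else vel.copy())
        frames.append(conf)
        times.append(step * dt)
        for c, v in zip(cols, (step, step * dt, e_bond, e_angle, e_pair, ke,
                               temp, radius_of_gyration(conf))):
            thermo[c].append(v)

    record(0)
    done = 0
    while done < steps:
        chunk = min(thermo_every, steps - done)
        noise = rng.standard_normal(size=(chunk, n, 3))
        if integrator == "langevin":
            _kernels.baoab_chunk(pos, vel, forces, noise, dt, c1, c2, *kernel_args)
        else:
            _kernels.overdamped_chunk(pos, forces, noise, dt, zeta, T_star, *kernel_args)
        done += chunk
        _check_finite(pos, done)
        e_bond, e_angle, e_pair, _ = _kernels.compute_forces_kernel(
            pos, *kernel_args, forces)
        record(done)

    thermo = {c: np.asarray(v) for c, v in thermo.items()}
    return Trajectory(frames=frames, times=times, thermo=thermo)
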