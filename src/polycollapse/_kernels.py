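"""Numba-compiled force and integrator kernels for the bead-spring chain.

Topology is implicit: beads 0..N-1 form a linear chain with bonds (i, i+1)
and angles (i-1, i, i+1).  Pair interactions exclude directly bonded (1-2)
neighbours; 1-3 pairs interact (the angle term acts on them as well).
Angle kinds are encoded as integers: 0 harmonic, 1 cosine, 2 stiff, all
functions of the deviation delta = pi - theta from the straight rest state.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ANGLE_HARMONIC = 0
ANGLE_COSINE = 1
ANGLE_STIFF = 2

#: pair distance (sigma units) below which the LJ force is considered singular
SINGULAR_DISTANCE = 1e-6


@njit(cache=True)
def compute_forces_kernel(pos, bond_k, bond_l0, k_theta, angle_kind,
                          eps, sig, rcut, forces):
    """Fill ``forces`` with -grad U; return (e_bond, e_angle, e_pair, singular).

    The LJ pair energy is shifted to zero at the cutoff.  ``singular`` is 1
    when any interacting pair is closer than SINGULAR_DISTANCE * sig.
    """
    n = pos.shape[0]
    forces[:] = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_pair = 0.0
    singular = 0

    # harmonic bonds
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_l0
        e_bond += 0.5 * bond_k * dr * dr
        if r > 0.0:
            f = -bond_k * dr / r
            forces[i + 1, 0] += f * dx
            forces[i + 1, 1] += f * dy
            forces[i + 1, 2] += f * dz
            forces[i, 0] -= f * dx
            forces[i, 1] -= f * dy
            forces[i, 2] -= f * dz

    # bending: angle at bead i between u = r_{i-1}-r_i and v = r_{i+1}-r_i;
    # straight chain has theta = pi, deviation delta = pi - theta
    if k_theta > 0.0:
        for i in range(1, n - 1):
            ux = pos[i - 1, 0] - pos[i, 0]
            uy = pos[i - 1, 1] - pos[i, 1]
            uz = pos[i - 1, 2] - pos[i, 2]
            vx = pos[i + 1, 0] - pos[i, 0]
            vy = pos[i + 1, 1] - pos[i, 1]
            vz = pos[i + 1, 2] - pos[i, 2]
            nu = math.sqrt(ux * ux + uy * uy + uz * uz)
            nv = math.sqrt(vx * vx + vy * vy + vz * vz)
            if nu == 0.0 or nv == 0.0:
                singular = 1
                continue
            ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            delta = math.pi - math.acos(ct)
            sd = math.sin(delta)
            # energy and dU/dcos(theta) = (dU/ddelta)/sin(delta)
            if angle_kind == ANGLE_HARMONIC:
                e_angle += 0.5 * k_theta * delta * delta
                if sd > 1e-8:
                    g = k_theta * delta / sd
                else:
                    g = k_theta  # delta/sin(delta) -> 1
            elif angle_kind == ANGLE_COSINE:
                e_angle += 0.5 * k_theta * (1.0 - math.cos(delta))
                g = 0.5 * k_theta
            else:  # stiff = 8*harmonic - 14*cosine
                e_angle += 4.0 * k_theta * delta * delta - 7.0 * k_theta * (1.0 - math.cos(delta))
                if sd > 1e-8:
                    g = (8.0 * k_theta * delta - 7.0 * k_theta * sd) / sd
                else:
                    g = k_theta  # small-delta limit 8K - 7K
            # F_k = -g * d(cos theta)/d r_k
            inu = 1.0 / nu
            inv = 1.0 / nv
            dux = (vx * inv - ct * ux * inu) * inu
            duy = (vy * inv - ct * uy * inu) * inu
            duz = (vz * inv - ct * uz * inu) * inu
            dvx = (ux * inu - ct * vx * inv) * inv
            dvy = (uy * inu - ct * vy * inv) * inv
            dvz = (uz * inu - ct * vz * inv) * inv
            forces[i - 1, 0] -= g * dux
            forces[i - 1, 1] -= g * duy
            forces[i - 1, 2] -= g * duz
            forces[i + 1, 0] -= g * dvx
            forces[i + 1, 1] -= g * dvy
            forces[i + 1, 2] -= g * dvz
            forces[i, 0] += g * (dux + dvx)
            forces[i, 1] += g * (duy + dvy)
            forces[i, 2] += g * (duz + dvz)

    # Lennard-Jones 12-6, shifted to zero at the cutoff, excluding 1-2 pairs
    rc2 = rcut * rcut
    sr6c = (sig * sig / rc2) ** 3
    eshift = 4.0 * eps * (sr6c * sr6c - sr6c)
    rmin = SINGULAR_DISTANCE * sig
    for i in range(n):
        for j in range(i + 2, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            if r2 < rmin * rmin:
                singular = 1
                continue
            sr2 = sig * sig / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            e_pair += 4.0 * eps * (sr12 - sr6) - eshift
            f = 24.0 * eps * (2.0 * sr12 - sr6) / r2
            forces[j, 0] += f * dx
            forces[j, 1] += f * dy
            forces[j, 2] += f * dz
            forces[i, 0] -= f * dx
            forces[i, 1] -= f * dy
            forces[i, 2] -= f * dz

    return e_bond, e_angle, e_pair, singular


@njit(cache=True)
def baoab_chunk(pos, vel, forces, noise, dt, c1, c2,
                bond_k, bond_l0, k_theta, angle_kind, eps, sig, rcut):
    """Advance ``noise.shape[0]`` BAOAB Langevin steps in place (m = 1).

    c1 = exp(-gamma dt), c2 = sqrt(T* (1 - c1^2)); gamma = 0, T* = 0 gives
    plain velocity Verlet.  ``forces`` must hold -grad U of the entering
    positions and holds that of the final positions on return.
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    half = 0.5 * dt
    for s in range(nsteps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
                pos[i, d] += half * vel[i, d]
                vel[i, d] = c1 * vel[i, d] + c2 * noise[s, i, d]
                pos[i, d] += half * vel[i, d]
        compute_forces_kernel(pos, bond_k, bond_l0, k_theta, angle_kind,
                              eps, sig, rcut, forces)
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]


@njit(cache=True)
def overdamped_chunk(pos, forces, noise, dt, zeta, T_star,
                     bond_k, bond_l0, k_theta, angle_kind, eps, sig, rcut):
    """Euler-Maruyama steps of the position-only overdamped dynamics.

    dx = F dt / zeta + sqrt(2 T* dt / zeta) eta, friction coefficient zeta.
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    mob = dt / zeta
    amp = math.sqrt(2.0 * T_star * dt / zeta)
    for s in range(nsteps):
        for i in range(n):
            for d in range(3):
                pos[i, d] += mob * forces[i, d] + amp * noise[s, i, d]
        compute_forces_kernel(pos, bond_k, bond_l0, k_theta, angle_kind,
                              eps, sig, rcut, forces)
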