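"""Mapping bead-spring simulation parameters onto the energy-model ratios.

A pearl-necklace chain simulated with bead diameter ``sigma``, pair
attraction ``epsilon`` and a three-body bending potential of coefficient
``K_theta`` maps onto the continuum energy scales as

    gamma_s = 16 epsilon / (pi sigma^2)
    gamma_b = K_theta * sigma
    gamma_e = E_fold / (3 sigma^2),  E_fold = 3 U_angle(delta = 120 deg)

The surface energy assumes an exposed bead loses 8 of ~12 close-packed
contacts at epsilon/2 per bead per contact (4 epsilon over the bead cross
section pi sigma^2/4).  The end fold is a generic three-bead hairpin whose
three angles all deviate 120 degrees from straight, exposing an area of
3 sigma^2.  Because bending and folding derive from the same potential, the
ratio k2 = gamma_b/(gamma_e sigma^3) is independent of K_theta and fixed by
the potential shape alone.

Three bending potentials are supported, as functions of the deviation
``delta = theta - theta0`` from the straight (theta0 = pi) rest state:

    harmonic:  U = (1/2) K_theta delta^2
    cosine:    U = (1/2) K_theta (1 - cos delta)
    stiff:     U = 8 U_harmonic - 14 U_cosine

All three agree to O(delta^2) at small deviations; over (0, pi] they order
cosine <= harmonic <= stiff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.integrate import quad

__all__ = [
    "BendingPotential",
    "MappedParams",
    "bending_energy",
    "map_sim_params",
    "persistence_length",
    "FOLD_DEVIATION",
]

VALID_KINDS = ("harmonic", "cosine", "stiff")

#: deviation from straight at each of the three generic end-fold angles
FOLD_DEVIATION = 2.0 * math.pi / 3.0  # 120 degrees

#: exposed end-fold area, units sigma^2
FOLD_AREA = 3.0


@dataclass(frozen=True)
class BendingPotential:
    """Three-body bending potential; ``K_theta`` in epsilon units.

    ``theta0`` is the rest bond angle (pi = straight chain); energies are
    functions of the deviation ``delta = theta0 - theta`` in [0, pi].
    """

    kind: str
    K_theta: float
    theta0: float = math.pi

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.K_theta < 0 or not math.isfinite(self.K_theta):
            raise ValueError(f"K_theta must be non-negative and finite, got {self.K_theta}")

    def energy(self, delta: float) -> float:
        """Bending energy at deviation ``delta`` (radians) from the rest angle."""
        if not 0.0 <= delta <= math.pi:
            raise ValueError(f"delta must be in [0, pi], got {delta}")
        K = self.K_theta
        if self.kind == "harmonic":
            return 0.5 * K * delta**2
        if self.kind == "cosine":
            return 0.5 * K * (1.0 - math.cos(delta))
        # stiff = 8*harmonic - 14*cosine
        return 4.0 * K * delta**2 - 7.0 * K * (1.0 - math.cos(delta))

    def denergy(self, delta: float) -> float:
        """dU/ddelta, used by the force field."""
        if not 0.0 <= delta <= math.pi:
            raise ValueError(f"delta must be in [0, pi], got {delta}")
        K = self.K_theta
        if self.kind == "harmonic":
            return K * delta
        if self.kind == "cosine":
            return 0.5 * K * math.sin(delta)
        return 8.0 * K * delta - 7.0 * K * math.sin(delta)


def bending_energy(pot: BendingPotential, delta: float) -> float:
    """Bending energy of ``pot`` at deviation ``delta`` in [0, pi] radians."""
    return pot.energy(delta)


@dataclass(frozen=True)
class MappedParams:
    """Continuum energy scales derived from simulation parameters."""

    gamma_s: float
    gamma_e: float
    gamma_b: float
    E_fold: float
    A_fold: float
    k1: float
    k2: float
    potential: BendingPotential
    epsilon: float
    sigma: float


def map_sim_params(
    pot: BendingPotential, epsilon: float = 1.0, sigma: float = 1.0
) -> MappedParams:
    """Map (bending potential, epsilon, sigma) to (gamma_s, gamma_e, gamma_b).

    For the harmonic potential this gives k1 = pi^3 K_theta / (72 epsilon)
    ~ 0.43066 K_theta/epsilon, reproducing k1 = 3.23, 6.46, 12.92 at
    K_theta = 7.5, 15, 30 (epsilon = 1).
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    gamma_s = 16.0 * epsilon / (math.pi * sigma**2)
    E_fold = 3.0 * pot.energy(FOLD_DEVIATION)
    A_fold = FOLD_AREA * sigma**2
    gamma_e = E_fold / A_fold
    gamma_b = pot.K_theta * sigma
    k1 = gamma_e / gamma_s
    if gamma_e == 0.0:
        k2 = 0.0 if gamma_b == 0.0 else math.inf
    else:
        k2 = gamma_b / (gamma_e * sigma**3)
    return MappedParams(
        gamma_s=gamma_s,
        gamma_e=gamma_e,
        gamma_b=gamma_b,
        E_fold=E_fold,
        A_fold=A_fold,
        k1=k1,
        k2=k2,
        potential=pot,
        epsilon=epsilon,
        sigma=sigma,
    )


def persistence_length(pot: BendingPotential, T_star: float = 1.0, l0: float = 1.0) -> float:
    """Discrete-chain persistence length lp = -l0 / ln<cos delta>.

    <cos delta> is the Boltzmann average over bending deviations on the unit
    sphere, weight sin(delta) exp(-U(delta)/T*), evaluated by adaptive
    quadrature (relative tolerance 1e-10).  In the stiff limit
    K_theta/T* >> 1 this tends to K_theta l0 / T*.  Returns NaN in the floppy
    limit where <cos delta> <= 0 (persistence length undefined).
    """
    if not T_star > 0:
        raise ValueError(f"T_star must be positive, got {T_star}")
    if not l0 > 0:
        raise ValueError(f"l0 must be positive, got {l0}")

    def weight(d: float) -> float:
        return math.sin(d) * math.exp(-pot.energy(d) / T_star)

    den, _ = quad(weight, 0.0, math.pi, epsabs=1e-14, epsrel=1e-10, limit=200)
    num, _ = quad(lambda d: math.cos(d) * weight(d), 0.0, math.pi, epsabs=1e-14, epsrel=1e-10, limit=200)
    mean_cos = num / den
    if mean_cos <= 1e-12:  # floppy limit: tangent correlations do not decay exponentially
        return math.nan
    return -l0 / math.log(mean_cos)
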