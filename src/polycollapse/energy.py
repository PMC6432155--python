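"""Free-energy functionals of the torus and bundle collapsed states.

A self-attractive semiflexible chain of contour length ``L`` and monomer
diameter ``sigma`` is idealized as a continuous tube of volume
``Vc = (pi/4) L* sigma^3`` (``L* = L/sigma``).  Its collapsed state is
scored by three energy penalties:

* ``gamma_s`` -- solvent-exposure (surface) energy per unit area,
* ``gamma_e`` -- end-fold energy per unit area (bundle end caps),
* ``gamma_b`` -- bending energy per unit curvature squared per unit length
  (torus winding).

All lengths below are in units of ``sigma`` and free energies in units of
``gamma_s sigma^2``.  With ``k1 = gamma_e/gamma_s``,
``k2 = gamma_b/(gamma_e sigma^3)`` and ``kb = k1 k2 = gamma_b/(gamma_s
sigma^3)``, the two variational free energies are

    Gt*(rt*) = (pi/2) L*/rt* + 64 pi^2 kb rt*^4 / L*        (torus)
    Gb*(rb*) = (pi/2) L*/rb* + 2 pi (1 + k1) rb*^2          (bundle)

both strictly convex, with closed-form minima

    rt* = (L*^2 / (512 pi kb))^(1/5),   Gt*min = (5 pi/8) L*/rt*
    rb* = (1/2) (L*/(1 + k1))^(1/3),    Gb*min = (3 pi/4) L*/rb*

The torus must not self-intersect (``R* >= 2 rt*``); when the unconstrained
minimum violates this the optimum is projected onto the boundary
``rt* = (L*/(16 pi))^(1/3)`` (convexity makes the boundary point the
constrained minimizer).  A globule is an optimized bundle whose
diameter-to-length ratio ``2 rb*/l* = 1/(1 + k1)`` reaches 0.5 or more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ChainSpec",
    "EnergyParams",
    "TorusGeometry",
    "BundleGeometry",
    "torus_free_energy",
    "torus_optimal_geometry",
    "bundle_free_energy",
    "bundle_optimal_geometry",
]

#: minimum admissible torus cross-section radius (one bead radius, sigma units)
MIN_TUBE_RADIUS = 0.5


@dataclass(frozen=True)
class ChainSpec:
    """Dimensionless chain: contour length ``L* = L/sigma`` with ``sigma = 1``."""

    L_star: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.L_star > 0 and math.isfinite(self.L_star)):
            raise ValueError(f"L_star must be positive and finite, got {self.L_star}")
        if self.sigma != 1.0:
            raise ValueError("sigma is the reduced length unit and must be 1.0")

    @property
    def volume(self) -> float:
        """Dimensionless chain volume Vc/sigma^3 = pi L*/4 (tube of diameter sigma)."""
        return math.pi * self.L_star / 4.0


@dataclass(frozen=True)
class EnergyParams:
    """Surface / end-fold / bending energy scales and their dimensionless ratios."""

    gamma_s: float
    gamma_e: float
    gamma_b: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gamma_s > 0 and math.isfinite(self.gamma_s)):
            raise ValueError("gamma_s must be positive and finite")
        for name in ("gamma_e", "gamma_b"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be non-negative and finite")

    @classmethod
    def from_ratios(cls, k1: float, k2: float, sigma: float = 1.0) -> "EnergyParams":
        """Build from (k1, k2) with gamma_s normalized to 1."""
        if k1 < 0 or k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        return cls(gamma_s=1.0, gamma_e=k1, gamma_b=k1 * k2 * sigma**3, sigma=sigma)

    @property
    def k1(self) -> float:
        """gamma_e / gamma_s."""
        return self.gamma_e / self.gamma_s

    @property
    def k2(self) -> float:
        """gamma_b / (gamma_e sigma^3); inf-free: 0 when gamma_e = gamma_b = 0."""
        if self.gamma_e == 0.0:
            return 0.0 if self.gamma_b == 0.0 else math.inf
        return self.gamma_b / (self.gamma_e * self.sigma**3)

    @property
    def kb(self) -> float:
        """gamma_b / (gamma_s sigma^3) = k1 k2, the torus bending scale."""
        return self.gamma_b / (self.gamma_s * self.sigma**3)


@dataclass(frozen=True)
class TorusGeometry:
    """Optimized torus: tube radius ``r_t``, centerline radius ``R`` (sigma units).

    ``constrained`` marks projection onto the non-self-intersection boundary
    R = 2 r_t; ``thin`` flags a tube thinner than one bead (r_t < 1/2), which
    is reported but not enforced; ``degenerate`` flags the kb <= 0 limit.
    """

    r_t: float
    R: float
    G: float
    constrained: bool = False
    thin: bool = field(default=False, compare=False)
    degenerate: bool = field(default=False, compare=False)

    @property
    def aspect_ratio(self) -> float:
        """R*/r*, the torus aspect ratio."""
        return self.R / self.r_t


@dataclass(frozen=True)
class BundleGeometry:
    """Optimized bundle: end-cap radius ``r_b`` and length ``l`` (sigma units)."""

    r_b: float
    l: float
    G: float
    degenerate: bool = field(default=False, compare=False)

    @property
    def diameter_ratio(self) -> float:
        """2 r_b / l; equals 1/(1+k1) at the optimum; >= 0.5 means globule."""
        return 2.0 * self.r_b / self.l

    @property
    def aspect_ratio(self) -> float:
        """l*/r*, the bundle aspect ratio."""
        return self.l / self.r_b

    @property
    def is_globule(self) -> bool:
        return self.diameter_ratio >= 0.5


def torus_free_energy(r_t: float, chain: ChainSpec, kb: float) -> float:
    """Dimensionless torus free energy Gt*(rt*) at fixed chain volume.

    Surface term (pi/2) L*/rt* plus bending term 64 pi^2 kb rt*^4/L*, where
    ``kb = gamma_b/(gamma_s sigma^3)``.  Strictly convex in ``r_t`` for
    ``kb > 0``.
    """
    if not r_t > 0:
        raise ValueError(f"r_t must be positive, got {r_t}")
    if kb < 0:
        raise ValueError(f"kb must be non-negative, got {kb}")
    L = chain.L_star
    return 0.5 * math.pi * L / r_t + 64.0 * math.pi**2 * kb * r_t**4 / L


def torus_optimal_geometry(chain: ChainSpec, kb: float) -> TorusGeometry:
    """Minimize the torus free energy subject to non-self-intersection R >= 2 r_t.

    Unconstrained minimum rt* = (L*^2/(512 pi kb))^(1/5); when it violates
    R >= 2 r_t (always for small kb) the boundary torus with
    rt* = (L*/(16 pi))^(1/3), R = 2 rt* is returned with ``constrained=True``.
    ``kb <= 0`` is degenerate (the bending term vanishes and the surface term
    alone decreases without bound in r_t): the boundary torus is returned
    flagged ``degenerate``.
    """
    if kb < 0:
        raise ValueError(f"kb must be non-negative, got {kb}")
    L = chain.L_star
    r_cap = (L / (16.0 * math.pi)) ** (1.0 / 3.0)  # R = 2 r_t boundary
    if kb == 0.0:
        r_t, constrained, degenerate = r_cap, True, True
    else:
        r_unc = (L**2 / (512.0 * math.pi * kb)) ** 0.2
        constrained = r_unc > r_cap
        r_t = r_cap if constrained else r_unc
        degenerate = False
    R = L / (8.0 * math.pi * r_t**2)
    G = torus_free_energy(r_t, chain, kb)
    return TorusGeometry(
        r_t=r_t,
        R=R,
        G=G,
        constrained=constrained,
        thin=r_t < MIN_TUBE_RADIUS,
        degenerate=degenerate,
    )


def bundle_free_energy(r_b: float, chain: ChainSpec, k1: float) -> float:
    """Dimensionless bundle free energy Gb*(rb*) at fixed chain volume.

    Lateral surface term (pi/2) L*/rb* plus end caps 2 pi rb*^2 (surface)
    and k1 * 2 pi rb*^2 (fold penalty).  Strictly convex in ``r_b``.
    """
    if not r_b > 0:
        raise ValueError(f"r_b must be positive, got {r_b}")
    if k1 < 0:
        raise ValueError(f"k1 must be non-negative, got {k1}")
    L = chain.L_star
    return 0.5 * math.pi * L / r_b + 2.0 * math.pi * (1.0 + k1) * r_b**2


def bundle_optimal_geometry(chain: ChainSpec, k1: float) -> BundleGeometry:
    """Minimize the bundle free energy: rb* = (1/2)(L*/(1+k1))^(1/3).

    The optimized bundle satisfies l* = L*/(4 rb*^2) (volume conservation)
    and the identity 2 rb*/l* = 1/(1+k1).  ``k1 = 0`` gives the shortest
    admissible bundle (l = 2 r_b), flagged ``degenerate``.
    """
    if k1 < 0:
        raise ValueError(f"k1 must be non-negative, got {k1}")
    L = chain.L_star
    r_b = 0.5 * (L / (1.0 + k1)) ** (1.0 / 3.0)
    l = L / (4.0 * r_b**2)
    G = bundle_free_energy(r_b, chain, k1)
    return BundleGeometry(r_b=r_b, l=l, G=G, degenerate=(k1 == 0.0))
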