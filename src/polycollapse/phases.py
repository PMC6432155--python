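"""Phase classification and exact phase boundaries in the (k1, k2) plane.

For each point (k1, k2, L*) the optimized torus and bundle free energies are
compared; the lower one wins.  Two overrides implement the model's limits:

* globule: the optimized bundle with ``2 rb*/l* = 1/(1+k1) >= 0.5`` is a
  globule, i.e. every point with ``k1 <= 1`` is labelled ``G`` regardless of
  the torus energy (the globule-bundle boundary is the horizontal line
  ``k1 = 1``, independent of ``k2`` and ``L*``);
* coexistence: when the torus and bundle minima differ by less than a
  relative band (default 5%) the state is labelled ``T&B``.

The exact torus-bundle boundary follows from equating the two minima,

    k2 = alpha^5 L*^(1/3) (8 + 8 k1)^(5/3) / k1,
    alpha = (6/5) (512 pi)^(-1/5),

equivalently k2 = (6/5)^5/(16 pi) * L*^(1/3) (1+k1)^(5/3) / k1, which for
large k1 reduces to the power law k2 ~ k1^(2/3).  On this curve the optimal
radii satisfy rb*/rt* = 6/5 exactly.  The torus geometric constraints
1/2 <= rt* <= R*/2 bound the admissible k1 range on the boundary:
2 pi (5/6)^3 - 1 (~2.636) <= k1 <= (5/6)^3 L* - 1 (~0.5787 L* - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .energy import (
    BundleGeometry,
    ChainSpec,
    TorusGeometry,
    bundle_optimal_geometry,
    torus_optimal_geometry,
)

__all__ = [
    "PhasePrediction",
    "PhaseDiagram",
    "AdmissibleRange",
    "classify_state",
    "globule_bundle_boundary",
    "torus_bundle_boundary",
    "torus_bundle_asymptote",
    "k1_admissible_range",
    "build_phase_diagram",
]

#: relative free-energy difference below which torus and bundle coexist (T&B)
DEFAULT_COEXISTENCE_BAND = 0.05

#: alpha^5 of the boundary curve: (6/5)^5 / (512 pi)
ALPHA5 = (6.0 / 5.0) ** 5 / (512.0 * math.pi)

PHASE_ORDER = ("G", "B", "T&B", "T")  # order of appearance along increasing k1


@dataclass(frozen=True)
class PhasePrediction:
    """Winning collapsed state at one (k1, k2, L*) point."""

    label: str  # one of "G", "B", "T", "T&B"
    G_torus: float
    G_bundle: float
    torus_geom: TorusGeometry
    bundle_geom: BundleGeometry
    coexistence_margin: float
    k1: float
    k2: float
    L_star: float


class AdmissibleRange(NamedTuple):
    """k1 interval on the torus-bundle boundary allowed by torus geometry."""

    k1_min: float
    k1_max: float
    empty: bool


def globule_bundle_boundary() -> float:
    """k1 value of the globule-bundle boundary (2 rb*/l* = 0.5 => k1 = 1)."""
    return 1.0


def torus_bundle_boundary(k1: float, L_star: float) -> float:
    """Exact k2 at which the optimized torus and bundle free energies are equal.

    k2 = alpha^5 L*^(1/3) (8 + 8 k1)^(5/3) / k1 with alpha^5 = (6/5)^5/(512 pi).
    """
    if not k1 > 0:
        raise ValueError(f"k1 must be positive, got {k1}")
    if not L_star > 0:
        raise ValueError(f"L_star must be positive, got {L_star}")
    return ALPHA5 * L_star ** (1.0 / 3.0) * (8.0 + 8.0 * k1) ** (5.0 / 3.0) / k1


def torus_bundle_asymptote(k1: float, L_star: float) -> float:
    """Large-k1 power law of the boundary: k2 = 32 alpha^5 L*^(1/3) k1^(2/3)."""
    if not k1 > 0:
        raise ValueError(f"k1 must be positive, got {k1}")
    if not L_star > 0:
        raise ValueError(f"L_star must be positive, got {L_star}")
    return 32.0 * ALPHA5 * L_star ** (1.0 / 3.0) * k1 ** (2.0 / 3.0)


def k1_admissible_range(L_star: float) -> AdmissibleRange:
    """Bounds on k1 along the boundary from 1/2 <= rt* <= R*/2.

    On the boundary rt* = (5/6) rb*; the non-self-intersection constraint
    rt*^3 <= L*/(16 pi) gives k1 >= 2 pi (5/6)^3 - 1, and the one-bead
    thickness constraint rt* >= 1/2 gives k1 <= (5/6)^3 L* - 1.
    """
    if not L_star > 0:
        raise ValueError(f"L_star must be positive, got {L_star}")
    c = (5.0 / 6.0) ** 3
    k1_min = 2.0 * math.pi * c - 1.0
    k1_max = c * L_star - 1.0
    return AdmissibleRange(k1_min, k1_max, empty=k1_max < k1_min)


def classify_state(
    k1: float,
    k2: float,
    L_star: float,
    band: float = DEFAULT_COEXISTENCE_BAND,
) -> PhasePrediction:
    """Label the minimum-free-energy state at (k1, k2, L*).

    The torus (constraint-projected if needed) and bundle minima are compared;
    points with k1 <= 1 are globules regardless of the comparison, and points
    with relative free-energy difference below ``band`` are torus-bundle
    coexistent (``T&B``).
    """
    if not (0 <= band < 1):
        raise ValueError(f"band must be in [0, 1), got {band}")
    if k1 < 0 or k2 < 0:
        raise ValueError("k1 and k2 must be non-negative")
    chain = ChainSpec(L_star)
    tg = torus_optimal_geometry(chain, k1 * k2)
    bg = bundle_optimal_geometry(chain, k1)
    margin = abs(tg.G - bg.G) / min(tg.G, bg.G)
    if k1 <= globule_bundle_boundary():
        label = "G"
    elif band > 0 and margin < band:
        label = "T&B"
    elif tg.G < bg.G:
        label = "T"
    else:
        label = "B"
    return PhasePrediction(
        label=label,
        G_torus=tg.G,
        G_bundle=bg.G,
        torus_geom=tg,
        bundle_geom=bg,
        coexistence_margin=margin,
        k1=k1,
        k2=k2,
        L_star=L_star,
    )


@dataclass(frozen=True)
class PhaseDiagram:
    """Grid of phase labels plus sampled exact boundary curves.

    ``labels`` has shape (len(k1_axis), len(k2_axis)); the auxiliary arrays
    share that shape and hold the optimized free energies and geometries.
    ``boundary_curves`` maps curve names to (k1 samples, k2 samples) arrays;
    the globule-bundle line is stored as the scalar k1 = 1 sampled over
    k2_axis.
    """

    k1_axis: np.ndarray
    k2_axis: np.ndarray
    labels: np.ndarray  # dtype '<U3'
    L_star: float
    band: float
    G_torus: np.ndarray
    G_bundle: np.ndarray
    r_t: np.ndarray
    R: np.ndarray
    r_b: np.ndarray
    l: np.ndarray
    boundary_curves: dict


def _boundary_curves(L_star: float, n_samples: int) -> dict:
    rng = k1_admissible_range(L_star)
    k1s = np.logspace(
        math.log10(max(rng.k1_min, 1e-6)),
        math.log10(max(rng.k1_max, rng.k1_min * 10.0)),
        n_samples,
    )
    exact = np.array([torus_bundle_boundary(k, L_star) for k in k1s])
    asym = np.array([torus_bundle_asymptote(k, L_star) for k in k1s])
    return {
        "globule_bundle_k1": globule_bundle_boundary(),
        "torus_bundle": (k1s, exact),
        "torus_bundle_asymptote": (k1s, asym),
    }


def build_phase_diagram(
    k1_grid: Sequence[float],
    k2_grid: Sequence[float],
    L_star: float,
    band: float = DEFAULT_COEXISTENCE_BAND,
    boundary_samples: int = 512,
) -> PhaseDiagram:
    """Classify every (k1, k2) grid cell and attach the exact boundary curves.

    Grids must be non-empty and strictly increasing.  Deterministic: the same
    inputs always yield identical arrays.
    """
    k1_axis = np.asarray(k1_grid, dtype=float)
    k2_axis = np.asarray(k2_grid, dtype=float)
    for name, ax in (("k1_grid", k1_axis), ("k2_grid", k2_axis)):
        if ax.ndim != 1 or ax.size == 0:
            raise ValueError(f"{name} must be a non-empty 1-D sequence")
        if ax.size > 1 and not np.all(np.diff(ax) > 0):
            raise ValueError(f"{name} must be strictly increasing")
        if not np.all(ax > 0):
            raise ValueError(f"{name} values must be positive")
    shape = (k1_axis.size, k2_axis.size)
    labels = np.empty(shape, dtype="<U3")
    arrs = {name: np.empty(shape) for name in ("G_torus", "G_bundle", "r_t", "R", "r_b", "l")}
    for i, k1 in enumerate(k1_axis):
        for j, k2 in enumerate(k2_axis):
            p = classify_state(k1, k2, L_star, band=band)
            labels[i, j] = p.label
            arrs["G_torus"][i, j] = p.G_torus
            arrs["G_bundle"][i, j] = p.G_bundle
            arrs["r_t"][i, j] = p.torus_geom.r_t
            arrs["R"][i, j] = p.torus_geom.R
            arrs["r_b"][i, j] = p.bundle_geom.r_b
            arrs["l"][i, j] = p.bundle_geom.l
    return PhaseDiagram(
        k1_axis=k1_axis,
        k2_axis=k2_axis,
        labels=labels,
        L_star=L_star,
        band=band,
        boundary_curves=_boundary_curves(L_star, boundary_samples),
        **arrs,
    )
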