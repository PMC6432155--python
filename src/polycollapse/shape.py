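"""Gyration-tensor shape descriptors, conformation classification, fixtures.

A bead cloud is classified as torus (T), bundle (B) or globule (G) from the
eigenvalues lambda1 >= lambda2 >= lambda3 of its gyration tensor plus two
geometric cues: the "donut hole" radius about the flattest axis and the
extent ratio along the principal axis.  The rules (thresholds collected in
``ClassifierThresholds``) are:

* globule -- all eigenvalues comparable (lambda1/lambda3 below a factor 3);
* torus   -- oblate (lambda1 ~ lambda2 >> lambda3) with an open hole of at
  least one bead diameter;
* bundle  -- prolate (lambda1 >> lambda2 ~ lambda3) with axial extent at
  least twice the transverse extent;
* otherwise ``unknown``.

Aspect-ratio estimators mirror the continuum model's geometry: for a torus
R* is the mean radial bead distance from the symmetry axis and r* the RMS
spread about the circle of radius R*; for a bundle l* is the extent along
the principal axis and r* = sqrt(2) x the RMS transverse radius (exact for
beads filling a uniform disc).

``generate_reference_structure`` builds seeded synthetic bead clouds --
a winding over the torus tube surface, a folded raster of parallel strands,
or a uniform ball -- used as ground truth for the classifier tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .bd import Configuration, radius_of_gyration
from .energy import BundleGeometry, TorusGeometry

__all__ = [
    "ShapeDescriptors",
    "ClassifiedShape",
    "ClassifierThresholds",
    "gyration_tensor",
    "classify_conformation",
    "classify_trajectory",
    "generate_reference_structure",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """All classification thresholds in one place (sigma units where dimensional)."""

    eigen_comparable: float = 3.0  # lambda1/lambda3 <= this => globule
    planar_ratio: float = 3.0      # lambda1/lambda2 <= this and lambda2/lambda3 >= this => oblate
    hole_min: float = 1.0          # torus needs hole_radius > this
    extent_ratio: float = 2.0      # bundle needs axial/transverse extent >= this
    degenerate_eps: float = 1e-9   # lambda2/lambda1 below this => collinear


@dataclass(frozen=True)
class ShapeDescriptors:
    """Gyration-tensor eigenstructure and derived geometric cues."""

    rg: float
    eigenvalues: np.ndarray        # descending, lambda1 >= lambda2 >= lambda3 >= 0
    eigenvectors: np.ndarray       # columns matching eigenvalues
    asphericity: float             # lambda1 - (lambda2 + lambda3)/2
    acylindricity: float           # lambda2 - lambda3
    hole_radius: float             # min radial distance from the lambda3 axis
    axial_extent: float            # bead extent along the lambda1 axis
    transverse_extent: float       # max extent along the lambda2/lambda3 axes
    degenerate: bool               # collinear configuration


@dataclass(frozen=True)
class ClassifiedShape:
    label: str                     # "T", "B", "G" or "unknown"
    aspect_ratio: Optional[float]  # R*/r* (torus) or l*/r* (bundle); None otherwise
    descriptors: ShapeDescriptors


def gyration_tensor(
    config: Configuration,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> ShapeDescriptors:
    """Eigen-decomposed second-moment tensor about the centre of mass."""
    pos = config.positions
    if pos.shape[0] < 4:
        raise ValueError("need at least 4 beads for shape descriptors")
    d = pos - pos.mean(axis=0)
    S = d.T @ d / pos.shape[0]
    evals, evecs = np.linalg.eigh(S)          # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rg = math.sqrt(float(evals.sum()))
    # radial distances about the flattest (lambda3) axis
    axis3 = evecs[:, 2]
    perp = d - np.outer(d @ axis3, axis3)
    rho = np.linalg.norm(perp, axis=1)
    proj1 = d @ evecs[:, 0]
    ext = [float(np.ptp(d @ evecs[:, k])) for k in range(3)]
    degenerate = evals[0] > 0 and evals[1] / evals[0] < thresholds.degenerate_eps
    return ShapeDescriptors(
        rg=rg,
        eigenvalues=evals,
        eigenvectors=evecs,
        asphericity=float(evals[0] - 0.5 * (evals[1] + evals[2])),
        acylindricity=float(evals[1] - evals[2]),
        hole_radius=float(rho.min()),
        axial_extent=float(np.ptp(proj1)),
        transverse_extent=float(max(ext[1], ext[2])),
        degenerate=degenerate,
    )


def _torus_aspect(pos: np.ndarray, axis: np.ndarray) -> float:
    """R*/r* about ``axis``: mean ring radius over RMS spread about the ring."""
    d = pos - pos.mean(axis=0)
    z = d @ axis
    rho = np.linalg.norm(d - np.outer(z, axis), axis=1)
    R = float(rho.mean())
    r = math.sqrt(float(np.mean((rho - R) ** 2 + z**2)))
    return R / r if r > 0 else math.inf


def _bundle_aspect(pos: np.ndarray, axis: np.ndarray) -> float:
    """l*/r* about ``axis``; r* = sqrt(2) * RMS transverse radius."""
    d = pos - pos.mean(axis=0)
    z = d @ axis
    rho = np.linalg.norm(d - np.outer(z, axis), axis=1)
    l = float(np.ptp(z))
    r = math.sqrt(2.0 * float(np.mean(rho**2)))
    return l / r if r > 0 else math.inf


def classify_conformation(
    config: Configuration,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> ClassifiedShape:
    """Rule-based torus / bundle / globule call for one configuration."""
    if config.n_beads < 10:
        raise ValueError("need at least 10 beads to classify a conformation")
    desc = gyration_tensor(config, thresholds)
    l1, l2, l3 = desc.eigenvalues
    pos = config.positions
    label = "unknown"
    aspect: Optional[float] = None
    if desc.degenerate:
        return ClassifiedShape("unknown", None, desc)
    tiny = 1e-12 * max(l1, 1.0)
    if l3 > tiny and l1 / l3 <= thresholds.eigen_comparable:
        label = "G"
    elif (
        l1 / max(l2, tiny) <= thresholds.planar_ratio
        and l2 / max(l3, tiny) >= thresholds.planar_ratio
        and desc.hole_radius > thresholds.hole_min
    ):
        label = "T"
        aspect = _torus_aspect(pos, desc.eigenvectors[:, 2])
    elif (
        l1 / max(l2, tiny) >= thresholds.planar_ratio
        and l2 / max(l3, tiny) <= thresholds.planar_ratio
        and desc.axial_extent >= thresholds.extent_ratio * desc.transverse_extent
    ):
        label = "B"
        aspect = _bundle_aspect(pos, desc.eigenvectors[:, 0])
    return ClassifiedShape(label, aspect, desc)


def classify_trajectory(
    frames: Sequence[Configuration],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    minority_fraction: float = 0.2,
) -> str:
    """Label a trajectory from its last third of frames.

    Returns the majority per-frame label; "T&B" when both torus and bundle
    appear and the minority of the two holds at least ``minority_fraction``
    of the T/B frames (a fluctuating, coexistent state).
    """
    if not frames:
        raise ValueError("no frames to classify")
    tail = list(frames)[max(0, len(frames) - max(1, len(frames) // 3)):]
    labels = [classify_conformation(f, thresholds).label for f in tail]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    n_t, n_b = counts.get("T", 0), counts.get("B", 0)
    if n_t and n_b and min(n_t, n_b) >= minority_fraction * (n_t + n_b):
        return "T&B"
    return max(counts, key=counts.get)


def generate_reference_structure(
    kind: str,
    geometry: Union[TorusGeometry, BundleGeometry, float, tuple],
    n_beads: int,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
) -> Configuration:
    """Synthetic bead cloud of a given kind, with Gaussian positional noise.

    * ``kind="T"``: beads wound over the surface of the torus tube (every
      bead exactly ``r`` from the centerline circle when noise is zero);
      geometry is a TorusGeometry or an ``(R, r)`` tuple.
    * ``kind="B"``: parallel strands rastered back and forth inside a disc
    of radius ``r``, spanning exactly ``l`` axially; geometry is a
      BundleGeometry or an ``(l, r)`` tuple.
    * ``kind="G"``: beads uniform in a ball; geometry is the radius.
    """
    rng = np.random.default_rng(seed)
    if kind == "T":
        if isinstance(geometry, TorusGeometry):
            R, r = geometry.R, geometry.r_t
        else:
            R, r = geometry
        if R <= 0 or r <= 0:
            raise ValueError("torus radii must be positive")
        if n_beads < int(2.0 * math.pi * R):
            raise ValueError("too few beads to trace the torus centerline")
        # windings chosen so consecutive beads are about one sigma apart
        length = n_beads * 1.0
        circ = 2.0 * math.pi * R
        n_wind = max(2.0, math.sqrt(max(length**2 - circ**2, 0.0)) / (2.0 * math.pi * r))
        t = np.arange(n_beads) / n_beads
        theta = 2.0 * math.pi * t
        phi = 2.0 * math.pi * n_wind * t
        rho = R + r * np.cos(phi)
        pos = np.column_stack(
            (rho * np.cos(theta), rho * np.sin(theta), r * np.sin(phi))
        )
    elif kind == "B":
        if isinstance(geometry, BundleGeometry):
            l, r = geometry.l, geometry.r_b
        else:
            l, r = geometry
        if l <= 0 or r <= 0:
            raise ValueError("bundle dimensions must be positive")
        per_strand = max(2, int(round(l)) + 1)
        n_strands = max(1, math.ceil(n_beads / per_strand))
        if n_beads < 2 * per_strand:
            raise ValueError("too few beads to raster the bundle strands")
        golden = math.pi * (3.0 - math.sqrt(5.0))
        z_line = np.linspace(-l / 2.0, l / 2.0, per_strand)
        chunks = []
        for s in range(n_strands):
            # sunflower arrangement: bead density uniform over the disc
            rad = r * math.sqrt((s + 0.5) / n_strands)
            ang = s * golden
            z = z_line if s % 2 == 0 else z_line[::-1]  # raster fold
            take = min(per_strand, n_beads - s * per_strand)
            chunk = np.column_stack(
                (np.full(take, rad * math.cos(ang)),
                 np.full(take, rad * math.sin(ang)),
                 z[:take])
            )
            chunks.append(chunk)
        pos = np.concatenate(chunks)[:n_beads]
    elif kind == "G":
        radius = float(geometry)
        if radius <= 0:
            raise ValueError("globule radius must be positive")
        if n_beads < 4:
            raise ValueError("too few beads for a globule cloud")
        u = rng.random(n_beads) ** (1.0 / 3.0)
        v = rng.normal(size=(n_beads, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pos = radius * u[:, None] * v
    else:
        raise ValueError(f"kind must be 'T', 'B' or 'G', got {kind!r}")
    if noise_sigma > 0:
        pos = pos + rng.normal(scale=noise_sigma, size=pos.shape)
    return Configuration(pos)
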