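"""Readers and writers: XYZ, LAMMPS-dump, thermo TSV, diagram TSV/CSV.

All numeric output uses the ``%.10g`` format so that every writer/reader
pair round-trips losslessly at 10 significant digits.  Dump files use the
minimal ``id type x y z`` column set with an orthogonal shrink-wrapped box.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .bd import Configuration, Trajectory
from .phases import PhaseDiagram

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_thermo_tsv",
    "read_thermo_tsv",
    "write_diagram_tsv",
    "read_diagram_tsv",
    "write_boundary_csv",
    "read_boundary_csv",
]

_G = "%.10g"

PathLike = Union[str, Path]

THERMO_COLUMNS = ("step", "time", "e_bond", "e_angle", "e_pair", "ke", "temp", "rg")

DIAGRAM_COLUMNS = ("k1", "k2", "label", "G_torus", "G_bundle", "r_t", "R", "r_b", "l")


def _frames_times(traj) -> Tuple[List[Configuration], List[float]]:
    if isinstance(traj, Trajectory):
        return traj.frames, list(traj.times)
    if isinstance(traj, Configuration):
        return [traj], [0.0]
    frames = list(traj)
    return frames, [float(i) for i in range(len(frames))]


def write_xyz(path: PathLike, traj, element: str = "C") -> None:
    """Write frames as concatenated XYZ blocks; comment line carries ``t=``."""
    frames, times = _frames_times(traj)
    with open(path, "w") as fh:
        for conf, t in zip(frames, times):
            fh.write(f"{conf.n_beads}\n")
            fh.write(f"t={_G % t}\n")
            for x, y, z in conf.positions:
                fh.write(f"{element} {_G % x} {_G % y} {_G % z}\n")


def read_xyz(path: PathLike) -> Tuple[List[Configuration], List[float]]:
    """Read a (multi-frame) XYZ file written by :func:`write_xyz`."""
    frames: List[Configuration] = []
    times: List[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        comment = lines[i + 1]
        t = 0.0
        for tok in comment.split():
            if tok.startswith("t="):
                t = float(tok[2:])
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Configuration(pos))
        times.append(t)
        i += n + 2
    return frames, times


def write_lammps_dump(path: PathLike, traj, dt: float = 1.0) -> None:
    """Write frames in the LAMMPS dump dialect (id type x y z, shrink-wrapped box).

    Timesteps are recovered from frame times divided by ``dt`` (rounded).
    """
    frames, times = _frames_times(traj)
    with open(path, "w") as fh:
        for conf, t in zip(frames, times):
            step = int(round(t / dt)) if dt > 0 else 0
            lo = conf.positions.min(axis=0)
            hi = conf.positions.max(axis=0)
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{conf.n_beads}\n")
            fh.write("ITEM: BOX BOUNDS ss ss ss\n")
            for d in range(3):
                fh.write(f"{_G % lo[d]} {_G % hi[d]}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i, (x, y, z) in enumerate(conf.positions, start=1):
                fh.write(f"{i} 1 {_G % x} {_G % y} {_G % z}\n")


def read_lammps_dump(path: PathLike) -> Tuple[List[Configuration], List[int]]:
    """Read the dump dialect written by :func:`write_lammps_dump`."""
    frames: List[Configuration] = []
    steps: List[int] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].startswith("ITEM: TIMESTEP"):
        step = int(lines[i + 1])
        n = int(lines[i + 3])
        header = lines[i + 8].split()[2:]  # after "ITEM: ATOMS"
        ix, iy, iz = header.index("x"), header.index("y"), header.index("z")
        iid = header.index("id")
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 9 + k].split()
            idx = int(parts[iid]) - 1
            pos[idx] = [float(parts[ix]), float(parts[iy]), float(parts[iz])]
        frames.append(Configuration(pos))
        steps.append(step)
        i += 9 + n
    return frames, steps


def write_thermo_tsv(path: PathLike, thermo: dict) -> None:
    """Write per-frame thermodynamic records as TSV."""
    n = len(thermo["step"])
    with open(path, "w") as fh:
        fh.write("\t".join(THERMO_COLUMNS) + "\n")
        for i in range(n):
            row = []
            for c in THERMO_COLUMNS:
                v = thermo[c][i]
                row.append(str(int(v)) if c == "step" else _G % v)
            fh.write("\t".join(row) + "\n")


def read_thermo_tsv(path: PathLike) -> dict:
    data = np.genfromtxt(path, delimiter="\t", names=True)
    if data.ndim == 0:
        data = data.reshape(1)
    return {c: np.asarray(data[c]) for c in data.dtype.names}


def write_diagram_tsv(path: PathLike, diagram: PhaseDiagram, version: str = "") -> None:
    """Serialize a phase-diagram grid: one row per (k1, k2) cell.

    A ``#``-prefixed metadata header records the model version, L* and the
    coexistence band; output is deterministic for identical inputs.
    """
    with open(path, "w") as fh:
        if version:
            fh.write(f"# polycollapse {version}\n")
        fh.write(f"# L_star={_G % diagram.L_star} band={_G % diagram.band}\n")
        fh.write(f"# grid={diagram.k1_axis.size}x{diagram.k2_axis.size}\n")
        fh.write("\t".join(DIAGRAM_COLUMNS) + "\n")
        for i, k1 in enumerate(diagram.k1_axis):
            for j, k2 in enumerate(diagram.k2_axis):
                fh.write(
                    "\t".join(
                        (
                            _G % k1,
                            _G % k2,
                            diagram.labels[i, j],
                            _G % diagram.G_torus[i, j],
                            _G % diagram.G_bundle[i, j],
                            _G % diagram.r_t[i, j],
                            _G % diagram.R[i, j],
                            _G % diagram.r_b[i, j],
                            _G % diagram.l[i, j],
                        )
                    )
                    + "\n"
                )


def read_diagram_tsv(path: PathLike) -> dict:
    """Read a diagram TSV back into columns (labels as strings)."""
    cols: dict = {c: [] for c in DIAGRAM_COLUMNS}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("k1\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(DIAGRAM_COLUMNS):
                continue
            for c, v in zip(DIAGRAM_COLUMNS, parts):
                cols[c].append(v if c == "label" else float(v))
    return {c: (np.asarray(v) if c != "label" else v) for c, v in cols.items()}


def write_boundary_csv(path: PathLike, diagram_or_curves, L_star: float = None) -> None:
    """Write the sampled exact torus-bundle boundary and its asymptote as CSV."""
    curves = (
        diagram_or_curves.boundary_curves
        if isinstance(diagram_or_curves, PhaseDiagram)
        else diagram_or_curves
    )
    k1s, exact = curves["torus_bundle"]
    _, asym = curves["torus_bundle_asymptote"]
    with open(path, "w") as fh:
        fh.write(f"# globule_bundle_k1={_G % curves['globule_bundle_k1']}\n")
        fh.write("k1,k2_exact,k2_asymptote\n")
        for a, b, c in zip(k1s, exact, asym):
            fh.write(f"{_G % a},{_G % b},{_G % c}\n")


def read_boundary_csv(path: PathLike) -> dict:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("k1,"):
                continue
            rows.append([float(v) for v in line.strip().split(",")])
    arr = np.asarray(rows)
    return {"k1": arr[:, 0], "k2_exact": arr[:, 1], "k2_asymptote": arr[:, 2]}
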