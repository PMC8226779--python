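"""Topology and trajectory input/output.

PDB topologies and XTC/DCD binary trajectories are read through MDAnalysis;
the residue/role classification on top is ours (see :mod:`maostraj.model`).

A documented plain-text frame format is provided for fixtures and for
round-tripping synthetic trajectories without binary files::

    natoms nframes
    time bx by bz        # one line per frame: time (ps) and box edges (Å)
    x y z                # natoms coordinate lines per frame, in Å
    ...

"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np

from .model import AtomTable, Trajectory

__all__ = [
    "load_topology",
    "read_trajectory",
    "read_text_trajectory",
    "write_text_trajectory",
    "write_sidecar",
]

logger = logging.getLogger(__name__)


def _guess_element(name: str) -> str:
    """Element from a PDB atom name: first alphabetic character, with a
    two-letter check against common heavy elements."""
    stripped = name.strip()
    alpha = "".join(c for c in stripped if c.isalpha()).upper()
    if not alpha:
        return ""
    if alpha[:2] in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN") and len(stripped) > 1:
        # Only trust two-letter symbols when the name starts in column 13,
        # which MDAnalysis normalises away; heuristically require the full
        # name to begin with the symbol.
        if stripped.upper().startswith(alpha[:2]):
            return alpha[:2]
    return alpha[0]


def load_topology(
    path: str | Path,
    *,
    catalytic_residues: Iterable[int] = (),
    hydropathy_overrides: dict[str, str] | None = None,
    solvent_role_map: dict[str, str] | None = None,
    vdw_radii: dict[str, float] | None = None,
) -> AtomTable:
    """Read a PDB file into a classified :class:`AtomTable`.

    Raises ``ValueError`` on zero atoms or an atom whose element cannot be
    resolved from either the element column or the atom name.  Unknown
    residues are classified ``organic`` and reported through the module
    logger.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if len(u.atoms) == 0:
        raise ValueError(f"no atoms in {path}")

    names = [a.name for a in u.atoms]
    elements = []
    for a in u.atoms:
        el = ""
        if hasattr(a, "element"):
            try:
                el = (a.element or "").strip().upper()
            except Exception:
                el = ""
        if not el:
            el = _guess_element(a.name)
        if not el:
            raise ValueError(f"cannot resolve element for atom {a.index} ({a.name!r})")
        elements.append(el)
    resnames = [a.resname for a in u.atoms]
    resids = [int(a.resid) for a in u.atoms]

    table = AtomTable.from_fields(
        names,
        elements,
        resnames,
        resids,
        catalytic_residues=catalytic_residues,
        hydropathy_overrides=hydropathy_overrides,
        solvent_role_map=solvent_role_map,
        vdw_radii=vdw_radii,
    )
    unknown = sorted(set(table.residue_name[table.role == "organic"]))
    if unknown:
        logger.info("residues classified as organic: %s", ", ".join(unknown))
    return table


def read_trajectory(
    topology: str | Path, trajectory: str | Path | None = None
) -> Trajectory:
    """Read a binary (XTC/DCD) or PDB trajectory through MDAnalysis."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory is None:
            u = mda.Universe(str(topology))
        else:
            u = mda.Universe(str(topology), str(trajectory))
    coords, times, boxes = [], [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        times.append(float(ts.time))
        dims = ts.dimensions
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            boxes.append([1e6, 1e6, 1e6])  # effectively non-periodic
        else:
            boxes.append([float(dims[0]), float(dims[1]), float(dims[2])])
    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(times), dtype=float)  # some writers omit times
    return Trajectory(np.asarray(coords), times, np.asarray(boxes))


def write_text_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the plain-text frame format (see module docstring)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames}\n")
        for f in range(traj.n_frames):
            b = traj.box[f]
            fh.write(f"{traj.times[f]:.6f} {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}\n")
            for x, y, z in traj.coords[f]:
                fh.write(f"{x:.8f} {y:.8f} {z:.8f}\n")


def read_text_trajectory(path: str | Path) -> Trajectory:
    """Read the plain-text frame format back into a :class:`Trajectory`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header, expected 'natoms nframes'")
        natoms, nframes = int(header[0]), int(header[1])
        coords = np.empty((nframes, natoms, 3))
        times = np.empty(nframes)
        box = np.empty((nframes, 3))
        for f in range(nframes):
            fields = fh.readline().split()
            if len(fields) == 4:
                times[f] = float(fields[0])
                box[f] = [float(v) for v in fields[1:4]]
            elif len(fields) == 1:
                times[f] = float(fields[0])
                box[f] = [1e6, 1e6, 1e6]
            else:
                raise ValueError(f"{path}: malformed time line in frame {f}")
            for a in range(natoms):
                coords[f, a] = [float(v) for v in fh.readline().split()]
    return Trajectory(coords, times, box)


def write_sidecar(path: str | Path, spec: dict) -> None:
    """Write a JSON sidecar recording the generator spec and seed."""
    Path(path).write_text(json.dumps(spec, indent=2, sort_keys=True) + "\n")
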