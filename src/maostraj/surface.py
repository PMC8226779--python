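"""Numerical solvent-accessible surface areas and their partitions.

SASA is computed with the Shrake–Rupley rolling-probe method on a
deterministic golden-spiral point set: for each atom, test points are placed
on the sphere of radius (r_vdw + probe) and counted exposed when they fall
outside every neighbouring atom's probe-expanded sphere.  Per-atom areas are
then summed by residue hydropathy class (SA_philic / SA_phobic, nm²) and
over the catalytic-triad residues (SA_catalytic, nm²) — the hydrophilic /
hydrophobic balance and the exposure of the catalytic Ser being the
surface-level observables that distinguish lipase states across solvent
environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomTable, Trajectory

__all__ = [
    "SurfaceFrame",
    "SurfaceSeries",
    "golden_spiral_points",
    "shrake_rupley",
    "partition_surface",
    "sa_catalytic",
    "surface_series",
]

A2_TO_NM2 = 0.01


@dataclass
class SurfaceFrame:
    """Partitioned surface areas for one frame, in nm²."""

    sasa_total: float
    sa_philic: float
    sa_phobic: float
    ratio: float | None  # None when sa_phobic == 0 (ratio undefined)


@dataclass
class SurfaceSeries:
    """Per-frame surface areas over a trajectory, in nm²."""

    times: np.ndarray
    sasa_total: np.ndarray
    sa_philic: np.ndarray
    sa_phobic: np.ndarray
    sa_catalytic: np.ndarray
    ratio: np.ndarray  # NaN where undefined


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform deterministic points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas in Å²."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = len(coords)
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    # any pair closer than this could occlude each other
    max_reach = 2.0 * (radii.max() + probe)
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d < 1e-6:
            raise ValueError(f"atoms {i} and {j} overlap at identical positions")
        if d < radii[i] + radii[j] + 2.0 * probe:
            neighbors[i].append(j)
            neighbors[j].append(i)

    areas = np.empty(n)
    for i in range(n):
        ri = radii[i] + probe
        pts = coords[i] + ri * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors[i]:
            rj = radii[j] + probe
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= rj * rj
            if not exposed.any():
                break
        areas[i] = exposed.sum() / n_points * 4.0 * np.pi * ri * ri
    return areas


def partition_surface(per_atom_area: np.ndarray, atoms: AtomTable) -> SurfaceFrame:
    """Sum per-atom areas (Å²) into hydrophilic/hydrophobic components (nm²).

    Only protein atoms contribute.  The philic/phobic ratio is ``None``
    (undefined) when the hydrophobic component is zero.
    """
    per_atom_area = np.asarray(per_atom_area, dtype=float)
    prot = atoms.role == "protein"
    philic = per_atom_area[prot & (atoms.hydropathy == "philic")].sum() * A2_TO_NM2
    phobic = per_atom_area[prot & (atoms.hydropathy == "phobic")].sum() * A2_TO_NM2
    total = philic + phobic
    ratio = philic / phobic if phobic > 0 else None
    return SurfaceFrame(total, philic, phobic, ratio)


def sa_catalytic(
    per_atom_area: np.ndarray, atoms: AtomTable, triad: tuple[int, ...]
) -> float:
    """Surface area (nm²) summed over the atoms of the triad residues."""
    per_atom_area = np.asarray(per_atom_area, dtype=float)
    total = 0.0
    for resid in triad:
        mask = atoms.residue_id == resid
        if not mask.any():
            raise ValueError(f"catalytic residue {resid} not found in topology")
        total += per_atom_area[mask].sum()
    return total * A2_TO_NM2


def surface_series(
    traj: Trajectory,
    atoms: AtomTable,
    triad: tuple[int, ...] = (),
    probe: float = 1.4,
    n_points: int = 960,
) -> SurfaceSeries:
    """Per-frame SASA partition over a trajectory (protein atoms only)."""
    prot_idx = np.flatnonzero(atoms.role == "protein")
    if prot_idx.size == 0:
        raise ValueError("no protein atoms for surface analysis")
    nt = traj.n_frames
    total = np.empty(nt)
    philic = np.empty(nt)
    phobic = np.empty(nt)
    cat = np.zeros(nt)
    ratio = np.empty(nt)
    for f in range(nt):
        areas_prot = shrake_rupley(
            traj.coords[f, prot_idx], atoms.vdw_radius[prot_idx], probe, n_points
        )
        areas = np.zeros(len(atoms))
        areas[prot_idx] = areas_prot
        part = partition_surface(areas, atoms)
        total[f], philic[f], phobic[f] = part.sasa_total, part.sa_philic, part.sa_phobic
        ratio[f] = np.nan if part.ratio is None else part.ratio
        if triad:
            cat[f] = sa_catalytic(areas, atoms, tuple(triad))
    return SurfaceSeries(traj.times.copy(), total, philic, phobic, cat, ratio)
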