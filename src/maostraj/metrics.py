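"""Superposition-based flexibility metrics: RMSD and RMSF.

Rigid-body translations and rotations are removed by Kabsch superposition
(SVD-based least-squares fit, with the reflection case corrected) before any
deviation or fluctuation is measured, so the metrics report internal motion
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Trajectory

__all__ = ["SeriesResult", "kabsch_superpose", "rmsd_series", "rmsf", "superpose_trajectory"]


@dataclass
class SeriesResult:
    """A per-frame metric series (RMSD) or per-atom profile (RMSF), in Å."""

    times: np.ndarray
    values: np.ndarray
    selection: np.ndarray
    reference: int | str


def _check_superposable(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    c = ref - ref.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("reference atoms are collinear; rotation is underdetermined")


def kabsch_superpose(
    ref: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det = +1) and
    ``t`` a translation such that ``mobile @ R.T + t`` minimises the
    (weighted) RMSD to ``ref`` over all rigid motions.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mobile must both be (N, 3)")
    _check_superposable(ref)
    if weights is None:
        w = np.full(len(ref), 1.0 / len(ref))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    c_ref = (w[:, None] * ref).sum(axis=0)
    c_mob = (w[:, None] * mobile).sum(axis=0)
    P = mobile - c_mob
    Q = ref - c_ref
    H = (P * w[:, None]).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = c_ref - R @ c_mob
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt((w[:, None] * (moved - ref) ** 2).sum()))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    selection: np.ndarray,
    ref_frame: int = 0,
    weights: np.ndarray | None = None,
) -> SeriesResult:
    """Per-frame Kabsch-minimised RMSD of a selection vs a reference frame."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if not (0 <= ref_frame < traj.n_frames):
        raise IndexError(f"reference frame {ref_frame} out of range")
    ref = traj.coords[ref_frame, selection]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, values[f] = kabsch_superpose(ref, traj.coords[f, selection], weights)
    return SeriesResult(traj.times.copy(), values, selection, ref_frame)


def superpose_trajectory(
    traj: Trajectory, selection: np.ndarray, ref_frame: int = 0
) -> np.ndarray:
    """Coordinates of ``selection`` with every frame fitted onto ``ref_frame``.

    Returns an array of shape (frames, len(selection), 3).
    """
    selection = np.asarray(selection, dtype=int)
    ref = traj.coords[ref_frame, selection]
    out = np.empty((traj.n_frames, selection.size, 3))
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(ref, traj.coords[f, selection])
        out[f] = traj.coords[f, selection] @ R.T + t
    return out


def rmsf(traj: Trajectory, selection: np.ndarray) -> SeriesResult:
    """Per-atom root-mean-square fluctuation about the time-average position.

    Frames are first superposed onto frame 0 over the same selection.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fitted = superpose_trajectory(traj, selection, ref_frame=0)
    mean_pos = fitted.mean(axis=0)
    values = np.sqrt(((fitted - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    return SeriesResult(traj.times.copy(), values, selection, "fit-to-frame-0")
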