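"""Boltzmann-inversion energy landscapes and string-method minimum energy paths.

A 2D free-energy landscape over two collective variables (by convention
x = backbone RMSD, y = catalytic-site surface area) is estimated from the
sampled probability density: E(x) = −kT ln(P(x)/P_max), in kT units at the
simulation temperature, referenced so the global minimum sits at zero.
Minimum energy paths between basins are relaxed with the zero-temperature
string method (steepest descent of equally spaced path images with
arc-length reparametrisation); the highest-energy point along the converged
path is the transition state, checked to be a first-order saddle (exactly
one negative Hessian eigenvalue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

__all__ = [
    "Landscape2D",
    "PathResult",
    "boltzmann_landscape",
    "landscape_from_energy",
    "find_minima",
    "string_mep",
    "transition_state",
    "KT_TO_KCAL_AT",
]

_MASK_WALL_KT = 5.0  # soft wall above the highest sampled energy


def KT_TO_KCAL_AT(temperature: float) -> float:
    """kcal/mol per kT at the given temperature (R·T with R in kcal/(mol·K))."""
    return 1.987204259e-3 * temperature


@dataclass
class Landscape2D:
    """Gridded probability density and energy over two collective variables."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    P: np.ndarray  # (nx, ny), sums to 1 over unmasked bins
    E: np.ndarray  # kT units, min over unmasked = 0; +inf on masked bins
    mask: np.ndarray  # True where no samples fell
    temperature: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class PathResult:
    """A relaxed string of images on a landscape."""

    images: np.ndarray  # (n_images, 2) in CV units
    energies: np.ndarray  # kT, bilinear interpolation on E
    ts_index: int
    converged: bool
    iterations: int


def boltzmann_landscape(
    samples: np.ndarray,
    grid: tuple[int, int] = (50, 50),
    temperature: float = 313.0,
    smooth_sigma: float = 0.0,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
    pad: float = 0.02,
) -> Landscape2D:
    """Invert a 2D sample density into an energy landscape in kT units.

    The grid spans the sampled range padded by ``pad`` (fraction per side)
    unless explicit ranges are given.  ``smooth_sigma`` (bins) optionally
    Gaussian-smooths the histogram before inversion.  Bins that stay empty
    are masked and assigned E = +inf.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be (n, 2)")
    if len(samples) < 100:
        raise ValueError("landscape inversion needs at least 100 samples")
    nx, ny = grid
    if nx < 10 or ny < 10:
        raise ValueError("grid must be at least 10×10")

    def _edges(v: np.ndarray, n: int, rng: tuple[float, float] | None) -> np.ndarray:
        if rng is None:
            lo, hi = float(v.min()), float(v.max())
            span = hi - lo or 1.0
            lo -= pad * span
            hi += pad * span
        else:
            lo, hi = rng
        return np.linspace(lo, hi, n + 1)

    x_edges = _edges(samples[:, 0], nx, x_range)
    y_edges = _edges(samples[:, 1], ny, y_range)
    H, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=[x_edges, y_edges])
    if np.count_nonzero(H) <= 1:
        raise ValueError("all samples fall in one bin: degenerate landscape")
    if smooth_sigma > 0:
        H = gaussian_filter(H, smooth_sigma)
    mask = H <= 0
    P = np.where(mask, 0.0, H)
    P = P / P.sum()
    E = np.full_like(P, np.inf)
    pmax = P.max()
    E[~mask] = -np.log(P[~mask] / pmax)
    return Landscape2D(x_edges, y_edges, P, E, mask, temperature)


def landscape_from_energy(
    energy: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    temperature: float = 313.0,
) -> Landscape2D:
    """Build a landscape directly from a gridded energy surface (kT units).

    Useful for analytic test surfaces; P is the implied Boltzmann density and
    E is re-referenced to its global minimum.
    """
    E = np.asarray(energy, dtype=float) - np.nanmin(energy)
    mask = ~np.isfinite(E)
    P = np.where(mask, 0.0, np.exp(-np.where(mask, 0.0, E)))
    P /= P.sum()
    return Landscape2D(np.asarray(x_edges), np.asarray(y_edges), P, E, mask, temperature)


def find_minima(
    landscape: Landscape2D, min_separation: int = 3
) -> list[tuple[float, float, float]]:
    """Local minima of E on the 8-neighbourhood, deduplicated and sorted.

    Masked bins are excluded as candidates and treated as impassable (+inf)
    neighbours.  Plateaus yield one representative per ``min_separation``
    window with a deterministic lowest-x-then-y tie-break.  Returns
    ``[(x, y, E), ...]`` sorted by E ascending.
    """
    E = landscape.E
    nx, ny = E.shape
    padded = np.full((nx + 2, ny + 2), np.inf)
    padded[1:-1, 1:-1] = np.where(landscape.mask, np.inf, E)
    candidates = []
    for i in range(nx):
        for j in range(ny):
            if landscape.mask[i, j]:
                continue
            e = E[i, j]
            nb = padded[i : i + 3, j : j + 3]
            if e <= nb.min():
                candidates.append((e, i, j))
    candidates.sort()
    kept: list[tuple[float, int, int]] = []
    for e, i, j in candidates:
        if all(max(abs(i - ki), abs(j - kj)) >= min_separation for _, ki, kj in kept):
            kept.append((e, i, j))
    xc, yc = landscape.x_centers, landscape.y_centers
    return [(float(xc[i]), float(yc[j]), float(e)) for e, i, j in kept]


def _filled_energy(landscape: Landscape2D, smooth_sigma: float) -> np.ndarray:
    """E with masked bins replaced by a soft wall, optionally smoothed."""
    E = landscape.E
    finite = E[~landscape.mask]
    wall = (finite.max() if finite.size else 0.0) + _MASK_WALL_KT
    filled = np.where(landscape.mask, wall, E)
    if smooth_sigma > 0:
        filled = gaussian_filter(filled, smooth_sigma)
    return filled


def _to_bins(landscape: Landscape2D, pts: np.ndarray) -> np.ndarray:
    """CV coordinates → fractional bin-index coordinates."""
    dx = landscape.x_edges[1] - landscape.x_edges[0]
    dy = landscape.y_edges[1] - landscape.y_edges[0]
    out = np.empty_like(np.atleast_2d(pts).astype(float))
    p = np.atleast_2d(pts)
    out[:, 0] = (p[:, 0] - landscape.x_centers[0]) / dx
    out[:, 1] = (p[:, 1] - landscape.y_centers[0]) / dy
    return out


def _from_bins(landscape: Landscape2D, pts: np.ndarray) -> np.ndarray:
    dx = landscape.x_edges[1] - landscape.x_edges[0]
    dy = landscape.y_edges[1] - landscape.y_edges[0]
    p = np.atleast_2d(pts).astype(float)
    out = np.empty_like(p)
    out[:, 0] = landscape.x_centers[0] + p[:, 0] * dx
    out[:, 1] = landscape.y_centers[0] + p[:, 1] * dy
    return out


def _reparametrize(images: np.ndarray) -> np.ndarray:
    """Redistribute images to equal arc length along the piecewise-linear path."""
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return images.copy()
    target = np.linspace(0.0, s[-1], len(images))
    out = np.empty_like(images)
    for d in range(images.shape[1]):
        out[:, d] = np.interp(target, s, images[:, d])
    return out


def string_mep(
    landscape: Landscape2D,
    start: tuple[float, float],
    end: tuple[float, float],
    n_images: int = 32,
    step: float = 0.1,
    tol: float | None = None,
    max_iter: int = 5000,
    smooth_sigma: float = 1.0,
) -> PathResult:
    """Zero-temperature string method between two landscape points.

    The string is relaxed in fractional bin-index coordinates so the two
    collective variables (with incommensurate units) are treated on an equal
    footing: images descend the bilinear-interpolated energy gradient
    (endpoints fixed) and are re-parametrised to equal arc length every
    iteration.  ``step`` is in bins; ``tol`` defaults to 1e-3 of the grid
    extent.  Masked bins act as a soft wall 5 kT above the highest sampled
    energy; a converged path forced through them is a hard error.
    """
    start_b = _to_bins(landscape, np.asarray(start, dtype=float))[0]
    end_b = _to_bins(landscape, np.asarray(end, dtype=float))[0]
    filled = _filled_energy(landscape, smooth_sigma)
    nx, ny = filled.shape
    if tol is None:
        # threshold scaled by the descent step: displacement per iteration is
        # step·|grad|, so this tests gradient smallness independent of step
        tol = 1e-3 * max(nx, ny) * step

    # energy interpolator in bin coordinates (grid spacing 1)
    interp = RegularGridInterpolator(
        (np.arange(nx, dtype=float), np.arange(ny, dtype=float)),
        filled,
        method="linear",
        bounds_error=False,
        fill_value=float(filled.max()),
    )

    def energy(pts: np.ndarray) -> np.ndarray:
        return interp(pts)

    def gradient(pts: np.ndarray, h: float = 0.5) -> np.ndarray:
        g = np.empty_like(pts)
        for d in range(2):
            off = np.zeros_like(pts)
            off[:, d] = h
            g[:, d] = (energy(pts + off) - energy(pts - off)) / (2.0 * h)
        return g

    if np.allclose(start_b, end_b):
        e0 = float(energy(start_b[None])[0])
        return PathResult(_from_bins(landscape, start_b[None]), np.array([e0]), 0, True, 0)
    if n_images < 8:
        raise ValueError("string method needs at least 8 images")

    images = np.linspace(start_b, end_b, n_images)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = gradient(images)
        disp = -step * grad
        np.clip(disp, -0.5, 0.5, out=disp)
        new = images + disp
        new[0], new[-1] = images[0], images[-1]
        new = _reparametrize(new)
        move = float(np.max(np.linalg.norm(new - images, axis=1)))
        images = new
        if move < tol:
            converged = True
            break

    energies = np.asarray(energy(images), dtype=float)
    finite = landscape.E[~landscape.mask]
    wall_floor = finite.max() if finite.size else 0.0
    if energies.max() > wall_floor + _MASK_WALL_KT / 2.0:
        raise RuntimeError(
            "minimum energy path is forced through unsampled (masked) bins "
            "with no finite-energy detour"
        )
    ts_index = int(np.argmax(energies))
    return PathResult(_from_bins(landscape, images), energies, ts_index, converged, it)


def transition_state(
    path: PathResult, landscape: Landscape2D, smooth_sigma: float = 1.0
) -> tuple[tuple[float, float], float, bool]:
    """Transition state of a converged path: its highest-energy image.

    Returns ``((x, y), energy_kT, saddle_check)`` where ``saddle_check`` is
    True when the finite-difference Hessian of the (smoothed) energy at the
    nearest grid bin has exactly one negative eigenvalue — i.e. the point is
    a first-order saddle.  An endpoint maximum is never reported as a saddle.
    """
    if not path.converged:
        raise ValueError("transition state requires a converged path")
    ts = path.images[path.ts_index]
    energy = float(path.energies[path.ts_index])
    if path.ts_index in (0, len(path.images) - 1):
        return (float(ts[0]), float(ts[1])), energy, False

    filled = _filled_energy(landscape, smooth_sigma)
    nx, ny = filled.shape
    dx = landscape.x_edges[1] - landscape.x_edges[0]
    dy = landscape.y_edges[1] - landscape.y_edges[0]
    b = _to_bins(landscape, ts[None])[0]
    i = int(np.clip(round(b[0]), 1, nx - 2))
    j = int(np.clip(round(b[1]), 1, ny - 2))
    d2x = (filled[i + 1, j] - 2 * filled[i, j] + filled[i - 1, j]) / dx**2
    d2y = (filled[i, j + 1] - 2 * filled[i, j] + filled[i, j - 1]) / dy**2
    dxy = (
        filled[i + 1, j + 1] - filled[i + 1, j - 1] - filled[i - 1, j + 1] + filled[i - 1, j - 1]
    ) / (4.0 * dx * dy)
    H = np.array([[d2x, dxy], [dxy, d2y]])
    eig = np.linalg.eigvalsh(H)
    thresh = 1e-9 * max(1.0, float(np.max(np.abs(eig))))
    n_negative = int(np.sum(eig < -thresh))
    return (float(ts[0]), float(ts[1])), energy, n_negative == 1
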