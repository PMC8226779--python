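"""Synthetic trajectories and time series with known ground truth.

Every downstream analysis stage (diffusion, hydration shells, hydrogen-bond
lifetimes, rotational relaxation, landscape inversion) can be validated
against a generator here whose statistical parameters are exact by
construction.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import AtomTable, Trajectory

__all__ = [
    "CM2S_TO_A2PS",
    "BrownianSpec",
    "ShellSpec",
    "PotentialSpec",
    "gen_brownian",
    "gen_shell_waters",
    "gen_cv_samples",
    "gen_hb_telegraph",
    "gen_rotational_diffusion",
    "gen_toy_peptide",
    "potential_function",
]

# Unit conversion for diffusion coefficients, fixed in one place:
# 1 cm²/s = 1e16 Å² / 1e12 ps = 1e4 Å²/ps.
CM2S_TO_A2PS = 1.0e4
assert CM2S_TO_A2PS == (1e8**2) / 1e12


@dataclass(frozen=True)
class BrownianSpec:
    """Isotropic translational diffusion of point particles in a cubic box."""

    n_particles: int
    D: float  # cm²/s
    dt: float  # ps
    n_frames: int
    box: float  # Å
    seed: int

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.box <= 0:
            raise ValueError("box must be positive")


@dataclass(frozen=True)
class ShellSpec:
    """Water oxygens in Gaussian radial shells around a single solute atom."""

    radii: tuple[float, ...]
    sigmas: tuple[float, ...]
    weights: tuple[float, ...]
    n_waters: int
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        sigmas = np.asarray(self.sigmas, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if len(radii) != len(sigmas) or len(radii) != len(weights):
            raise ValueError("radii, sigmas, weights must have equal length")
        if np.any(radii <= 0):
            raise ValueError("shell radii must be positive")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("shell radii must be strictly increasing")
        if np.any(sigmas <= 0):
            raise ValueError("shell sigmas must be positive")
        if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
            raise ValueError("weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class PotentialSpec:
    """A bounded-below 2D potential sampled at a Boltzmann temperature.

    The potential is expressed in units of kT at ``temperature``, so the
    target density is simply ``exp(-V)``.
    """

    form: str = "double_well"
    parameters: dict = field(default_factory=dict)
    temperature: float = 313.0

    def __post_init__(self) -> None:
        if self.form not in ("double_well", "harmonic", "gaussian_mixture"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def potential_function(spec: PotentialSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Return V(points) for an (n, 2) array of collective-variable points.

    Forms (all in kT units):

    * ``harmonic``:  k/2 (x² + y²), parameter ``k`` (default 1);
    * ``double_well``:  a (x² − 1)² + b y², parameters ``a``, ``b`` (default 1);
    * ``gaussian_mixture``:  −ln Σᵢ wᵢ N((x,y); μᵢ, σᵢ²I), parameters
      ``means``, ``sigmas``, ``weights``.
    """
    p = spec.parameters
    if spec.form == "harmonic":
        k = float(p.get("k", 1.0))

        def V(x: np.ndarray) -> np.ndarray:
            x = np.atleast_2d(x)
            return 0.5 * k * (x[:, 0] ** 2 + x[:, 1] ** 2)

    elif spec.form == "double_well":
        a = float(p.get("a", 1.0))
        b = float(p.get("b", 1.0))

        def V(x: np.ndarray) -> np.ndarray:
            x = np.atleast_2d(x)
            return a * (x[:, 0] ** 2 - 1.0) ** 2 + b * x[:, 1] ** 2

    else:  # gaussian_mixture
        means = np.asarray(p.get("means", [[-1.0, 0.0], [1.0, 0.0]]), dtype=float)
        sigmas = np.asarray(p.get("sigmas", [0.5] * len(means)), dtype=float)
        weights = np.asarray(p.get("weights", [1.0 / len(means)] * len(means)), dtype=float)
        weights = weights / weights.sum()

        def V(x: np.ndarray) -> np.ndarray:
            x = np.atleast_2d(x)
            d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
            dens = (weights / (2 * np.pi * sigmas**2)) * np.exp(-d2 / (2 * sigmas**2))
            return -np.log(dens.sum(axis=1) + 1e-300)

    return V


def gen_brownian(spec: BrownianSpec) -> Trajectory:
    """Independent Gaussian random walks with per-step displacement variance
    2·D·dt per dimension.

    The returned trajectory carries wrapped coordinates in ``coords`` and the
    unwrapped walk in ``unwrapped``.  A sampled step larger than half the box
    in any component is a hard error: the minimum-image convention could not
    recover the true displacement and the MSD would be undefined.
    """
    rng = np.random.default_rng(spec.seed)
    d_a2ps = spec.D * CM2S_TO_A2PS
    sigma = math.sqrt(2.0 * d_a2ps * spec.dt)
    start = rng.uniform(0.0, spec.box, size=(spec.n_particles, 3))
    steps = rng.normal(0.0, sigma, size=(spec.n_frames - 1, spec.n_particles, 3)) if sigma > 0 else np.zeros(
        (spec.n_frames - 1, spec.n_particles, 3)
    )
    if steps.size and np.max(np.abs(steps)) > spec.box / 2.0:
        raise ValueError("per-step displacement exceeds box/2; increase box or decrease D·dt")
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)], axis=0)
    wrapped = np.mod(unwrapped, spec.box)
    times = np.arange(spec.n_frames, dtype=float) * spec.dt
    box = np.full((spec.n_frames, 3), float(spec.box))
    return Trajectory(wrapped, times, box, unwrapped=unwrapped)


def gen_shell_waters(spec: ShellSpec, box: float | None = None) -> Trajectory:
    """Water oxygens in Gaussian radial shells around a solute at the origin.

    Atom 0 is the solute; atoms 1..n_waters are water oxygens whose radial
    distances follow the Gaussian mixture (negative draws rejected) with
    directions uniform on the sphere, independently per frame.
    """
    rng = np.random.default_rng(spec.seed)
    radii = np.asarray(spec.radii)
    sigmas = np.asarray(spec.sigmas)
    weights = np.asarray(spec.weights)
    if box is None:
        box = 2.0 * float(radii[-1] + 6.0 * sigmas.max()) + 10.0
    n_total = spec.n_waters * spec.n_frames

    comp = rng.choice(len(radii), size=n_total, p=weights)
    r = rng.normal(radii[comp], sigmas[comp])
    bad = r <= 0
    while np.any(bad):  # rejection of non-physical negative radii
        r[bad] = rng.normal(radii[comp[bad]], sigmas[comp[bad]])
        bad = r <= 0

    # uniform directions on the sphere
    u = rng.normal(size=(n_total, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    waters = (r[:, None] * u).reshape(spec.n_frames, spec.n_waters, 3)

    coords = np.zeros((spec.n_frames, spec.n_waters + 1, 3))
    coords[:, 1:, :] = waters
    # place everything at the box centre so wrapped == unwrapped
    coords += box / 2.0
    times = np.arange(spec.n_frames, dtype=float)
    boxes = np.full((spec.n_frames, 3), float(box))
    atoms = AtomTable.from_fields(
        names=["C"] + ["O"] * spec.n_waters,
        elements=["C"] + ["O"] * spec.n_waters,
        residue_names=["UNK"] + ["HOH"] * spec.n_waters,
        residue_ids=list(range(spec.n_waters + 1)),
    )
    return Trajectory(coords, times, boxes, atoms=atoms)


def gen_cv_samples(
    spec: PotentialSpec,
    n_samples: int,
    seed: int,
    *,
    x0: tuple[float, float] = (0.0, 0.0),
    initial_step: float = 0.5,
) -> np.ndarray:
    """Metropolis samples from exp(−V) for a 2D potential in kT units.

    The proposal step is auto-tuned during burn-in (10 % of ``n_samples``)
    toward an acceptance rate of 0.3–0.5; an overall acceptance rate outside
    [0.05, 0.95] after tuning is a hard error.  Returns an (n_samples, 2)
    array.
    """
    if n_samples == 0:
        return np.empty((0, 2))
    V = potential_function(spec)
    rng = np.random.default_rng(seed)
    n_burn = max(100, n_samples // 10)
    step = float(initial_step)

    x = np.asarray(x0, dtype=float)
    vx = float(V(x[None])[0])

    # burn-in with step tuning every 100 proposals
    accepted_window = 0
    for i in range(n_burn):
        prop = x + rng.normal(0.0, step, size=2)
        vp = float(V(prop[None])[0])
        if math.log(rng.uniform()) < vx - vp:
            x, vx = prop, vp
            accepted_window += 1
        if (i + 1) % 100 == 0:
            rate = accepted_window / 100.0
            if rate < 0.3:
                step *= 0.8
            elif rate > 0.5:
                step *= 1.25
            accepted_window = 0

    samples = np.empty((n_samples, 2))
    accepted = 0
    for i in range(n_samples):
        prop = x + rng.normal(0.0, step, size=2)
        vp = float(V(prop[None])[0])
        if math.log(rng.uniform()) < vx - vp:
            x, vx = prop, vp
            accepted += 1
        samples[i] = x
    rate = accepted / n_samples
    if rate < 0.05 or rate > 0.95:
        raise RuntimeError(f"Metropolis acceptance rate {rate:.3f} outside [0.05, 0.95]")
    return samples


def gen_hb_telegraph(
    tau_on: float,
    dt: float,
    n_frames: int,
    n_bonds: int,
    seed: int,
    tau_off: float | None = None,
) -> np.ndarray:
    """Boolean bond-existence matrix from independent telegraph processes.

    A formed bond breaks per frame with probability 1 − exp(−dt/tau_on); a
    broken bond reforms with probability 1 − exp(−dt/tau_off) (default
    tau_off = tau_on).  All bonds start formed.  Shape: (n_bonds, n_frames).
    """
    if tau_on <= 0:
        raise ValueError("tau_on must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau_off is None:
        tau_off = tau_on
    p_break = 1.0 - math.exp(-dt / tau_on)
    p_form = 1.0 - math.exp(-dt / tau_off)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n_bonds, n_frames - 1))
    h = np.empty((n_bonds, n_frames), dtype=bool)
    h[:, 0] = True
    for t in range(1, n_frames):
        on = h[:, t - 1]
        h[:, t] = np.where(on, u[:, t - 1] >= p_break, u[:, t - 1] < p_form)
    return h


def gen_rotational_diffusion(
    D_r: float, dt: float, n_frames: int, n_vectors: int, seed: int
) -> np.ndarray:
    """Unit vectors undergoing isotropic rotational diffusion.

    Each step applies a random rotation whose rotation vector has i.i.d.
    Gaussian components of variance 2·D_r·dt, the small-step propagator of
    rotational diffusion; the orientational correlation functions then decay
    as C_l(t) = exp(−l(l+1)·D_r·t).  Vectors are renormalised every frame.
    Shape: (n_frames, n_vectors, 3).
    """
    if D_r < 0:
        raise ValueError("D_r must be non-negative")
    if D_r * dt > 0.1:
        raise ValueError("D_r·dt > 0.1: time step too coarse for the small-angle propagator")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_vectors, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    out = np.empty((n_frames, n_vectors, 3))
    out[0] = v
    sigma = math.sqrt(2.0 * D_r * dt)
    for t in range(1, n_frames):
        if sigma == 0:
            out[t] = out[t - 1]
            continue
        omega = rng.normal(0.0, sigma, size=(n_vectors, 3))
        theta = np.linalg.norm(omega, axis=1, keepdims=True)
        axis = omega / np.where(theta > 0, theta, 1.0)
        v = out[t - 1]
        ct = np.cos(theta)
        st = np.sin(theta)
        # Rodrigues rotation of each vector about its own random axis
        v_new = (
            v * ct
            + np.cross(axis, v) * st
            + axis * (axis * v).sum(axis=1, keepdims=True) * (1.0 - ct)
        )
        v_new /= np.linalg.norm(v_new, axis=1, keepdims=True)
        out[t] = v_new
    return out


_TOY_SEQUENCE = ("SER", "LEU", "HIS", "GLY", "ASP")
_RES_ATOMS = {  # minimal heavy-atom sketches (name, element, local offset Å)
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
    "LEU": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C")],
    "HIS": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("ND1", "N")],
    "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    "ASP": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OD1", "O")],
}


def gen_toy_peptide(
    n_frames: int = 1,
    seed: int = 0,
    jitter: float = 0.15,
    catalytic_residues: tuple[int, ...] = (1, 3, 5),
) -> Trajectory:
    """A 5-residue Ser-Leu-His-Gly-Asp peptide with a jittered trajectory.

    A geometric sketch (not a physical structure): residues are laid out
    along x at 3.8 Å CA spacing with side-chain atoms fanned out.  Useful as
    a small protein-like fixture for superposition, fluctuation and surface
    analyses.  ``jitter`` is the per-atom Gaussian displacement s.d. (Å)
    applied to frames 1.. relative to frame 0.
    """
    names, elements, resnames, resids, base = [], [], [], [], []
    for ri, resname in enumerate(_TOY_SEQUENCE, start=1):
        cx = 3.8 * (ri - 1)
        for ai, (aname, el) in enumerate(_RES_ATOMS[resname]):
            names.append(aname)
            elements.append(el)
            resnames.append(resname)
            resids.append(ri)
            # fan atoms around the CA position; deterministic layout
            ang = 2.1 * ai
            base.append([cx + 0.9 * math.cos(ang), 1.2 * math.sin(ang), 0.7 * ai % 2.5])
    base = np.asarray(base)
    rng = np.random.default_rng(seed)
    coords = np.repeat(base[None], n_frames, axis=0)
    if n_frames > 1 and jitter > 0:
        coords[1:] += rng.normal(0.0, jitter, size=coords[1:].shape)
    coords += 25.0  # centre in the box
    atoms = AtomTable.from_fields(
        names, elements, resnames, resids, catalytic_residues=catalytic_residues
    )
    times = np.arange(n_frames, dtype=float)
    box = np.full((n_frames, 3), 50.0)
    return Trajectory(coords, times, box, atoms=atoms)
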