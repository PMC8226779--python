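"""Core data model: atom tables, trajectories and atom selections.

Conventions used throughout the package:

* lengths in Å, times in ps, surface areas reported in nm²,
  diffusion coefficients reported in cm²/s;
* atom indices are 0-based;
* boxes are orthorhombic, described by three edge lengths per frame, with
  the minimum-image convention applied wherever distances cross the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomTable",
    "Trajectory",
    "SelectionError",
    "select",
    "minimum_image",
    "STANDARD_AA",
    "PHOBIC_RESIDUES",
    "WATER_RESIDUES",
    "ION_RESIDUES",
    "BONDI_RADII",
    "DEFAULT_VDW_RADIUS",
]

# Standard amino acids (3-letter codes)
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Hydrophobic residues by the sign of the Kyte–Doolittle scale (plus GLY/CYS,
# which the scale places on the hydrophobic side); everything else standard is
# hydrophilic.  Overridable per-residue through configuration.
PHOBIC_RESIDUES = frozenset("ALA VAL LEU ILE PRO PHE MET TRP GLY CYS".split())

WATER_RESIDUES = frozenset("HOH WAT SOL TIP3 TIP4 SPC T3P".split())
ION_RESIDUES = frozenset("NA CL K MG CA ZN NA+ CL- K+ MG2 CA2 SOD CLA POT".split())

# Bondi van der Waals radii (Å) for the elements that occur in protein/solvent
# systems; anything absent falls back to DEFAULT_VDW_RADIUS.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
}
DEFAULT_VDW_RADIUS = 1.7

_BACKBONE_NAMES = {"C", "CA", "N"}


class SelectionError(ValueError):
    """Raised for malformed or empty atom selections."""


@dataclass
class AtomTable:
    """Per-atom metadata for a simulation system.

    All fields are numpy arrays of equal length (one entry per atom).
    ``hydropathy`` is ``"philic"``/``"phobic"`` for protein atoms and ``""``
    otherwise; ``role`` is one of ``protein``, ``water``, ``organic``, ``ion``.
    """

    name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_id: np.ndarray
    vdw_radius: np.ndarray
    hydropathy: np.ndarray
    role: np.ndarray
    is_backbone: np.ndarray
    is_catalytic: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.name)
        for f in (
            "element",
            "residue_name",
            "residue_id",
            "vdw_radius",
            "hydropathy",
            "role",
            "is_backbone",
            "is_catalytic",
        ):
            if len(getattr(self, f)) != n:
                raise ValueError(f"AtomTable field {f!r} has inconsistent length")
        if n and not np.all(self.vdw_radius > 0):
            raise ValueError("vdw_radius must be positive for every atom")
        prot = self.role == "protein"
        if n and not np.all(np.isin(self.hydropathy[prot], ["philic", "phobic"])):
            raise ValueError("every protein atom needs a hydropathy class")

    def __len__(self) -> int:
        return len(self.name)

    @property
    def atom_id(self) -> np.ndarray:
        return np.arange(len(self), dtype=int)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "atom_id": self.atom_id,
                "name": self.name,
                "element": self.element,
                "residue_name": self.residue_name,
                "residue_id": self.residue_id,
                "vdw_radius": self.vdw_radius,
                "hydropathy": self.hydropathy,
                "role": self.role,
                "is_backbone": self.is_backbone,
                "is_catalytic": self.is_catalytic,
            }
        )

    @classmethod
    def from_fields(
        cls,
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        *,
        catalytic_residues: Iterable[int] = (),
        hydropathy_overrides: dict[str, str] | None = None,
        solvent_role_map: dict[str, str] | None = None,
        vdw_radii: dict[str, float] | None = None,
    ) -> "AtomTable":
        """Build a classified table from raw per-atom records.

        Classification rules: standard amino-acid residues are ``protein``
        (with Kyte–Doolittle-sign hydropathy), recognized water residue names
        are ``water``, recognized monoatomic ions are ``ion``, everything else
        is ``organic``.  Backbone atoms are exactly the atoms named C, CA, N
        inside protein residues.
        """
        names = np.asarray([str(x).strip().upper() for x in names], dtype=object)
        elements = np.asarray([str(x).strip().upper() for x in elements], dtype=object)
        resnames = np.asarray([str(x).strip().upper() for x in residue_names], dtype=object)
        resids = np.asarray(residue_ids, dtype=int)
        n = len(names)
        if n == 0:
            raise ValueError("empty atom table")

        overrides = {k.upper(): v for k, v in (hydropathy_overrides or {}).items()}
        role_map = {k.upper(): v for k, v in (solvent_role_map or {}).items()}
        radii_table = dict(BONDI_RADII)
        if vdw_radii:
            radii_table.update({k.upper(): float(v) for k, v in vdw_radii.items()})
        catalytic = set(int(r) for r in catalytic_residues)

        role = np.empty(n, dtype=object)
        hydro = np.empty(n, dtype=object)
        radius = np.empty(n, dtype=float)
        backbone = np.zeros(n, dtype=bool)
        is_cat = np.zeros(n, dtype=bool)

        for i in range(n):
            rn = resnames[i]
            if rn in role_map:
                role[i] = role_map[rn]
            elif rn in STANDARD_AA:
                role[i] = "protein"
            elif rn in WATER_RESIDUES:
                role[i] = "water"
            elif rn in ION_RESIDUES:
                role[i] = "ion"
            else:
                role[i] = "organic"
            if role[i] == "protein":
                if rn in overrides:
                    hydro[i] = overrides[rn]
                else:
                    hydro[i] = "phobic" if rn in PHOBIC_RESIDUES else "philic"
                backbone[i] = names[i] in _BACKBONE_NAMES
            else:
                hydro[i] = ""
            el = elements[i]
            if not el:
                raise ValueError(f"atom {i} ({names[i]}) has no element")
            radius[i] = radii_table.get(el, DEFAULT_VDW_RADIUS)
            is_cat[i] = resids[i] in catalytic

        return cls(
            name=names,
            element=elements,
            residue_name=resnames,
            residue_id=resids,
            vdw_radius=radius,
            hydropathy=hydro,
            role=role,
            is_backbone=backbone,
            is_catalytic=is_cat,
        )


@dataclass
class Trajectory:
    """Cartesian coordinates over time.

    ``coords`` has shape (frames, atoms, 3) in Å; ``times`` is per-frame time
    in ps (strictly increasing); ``box`` holds per-frame orthorhombic edge
    lengths in Å.  ``unwrapped`` (optional) carries the same coordinates
    without periodic wrapping, for mean-square-displacement analysis.
    """

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray
    unwrapped: np.ndarray | None = None
    atoms: AtomTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (frames, 3)")
        if self.times.shape != (self.n_frames,):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        if self.unwrapped is not None:
            self.unwrapped = np.asarray(self.unwrapped, dtype=float)
            if self.unwrapped.shape != self.coords.shape:
                raise ValueError("unwrapped coords must match coords in shape")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def minimum_image(vecs: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return vecs
    box = np.asarray(box, dtype=float)
    return vecs - box * np.round(vecs / box)


_KEYWORDS = {"backbone", "water_oxygen", "protein", "water", "organic", "ion", "catalytic", "all"}


def _term_mask(atoms: AtomTable, tokens: list[str], pos: int) -> tuple[np.ndarray, int]:
    tok = tokens[pos]
    if tok == "resid":
        if pos + 1 >= len(tokens):
            raise SelectionError("'resid' needs a residue id or range, e.g. 'resid 5:10'")
        spec = tokens[pos + 1]
        try:
            if ":" in spec:
                lo_s, hi_s = spec.split(":", 1)
                lo, hi = int(lo_s), int(hi_s)
            elif "-" in spec[1:]:  # 5-10 style range (not a bare negative id)
                cut = spec.index("-", 1)
                lo, hi = int(spec[:cut]), int(spec[cut + 1 :])
            else:
                lo = hi = int(spec)
        except ValueError as exc:
            raise SelectionError(f"bad resid range {spec!r}") from exc
        return (atoms.residue_id >= lo) & (atoms.residue_id <= hi), pos + 2
    if tok == "backbone":
        return atoms.is_backbone.copy(), pos + 1
    if tok == "water_oxygen":
        return (atoms.role == "water") & (atoms.element == "O"), pos + 1
    if tok == "catalytic":
        return atoms.is_catalytic.copy(), pos + 1
    if tok == "all":
        return np.ones(len(atoms), dtype=bool), pos + 1
    if tok in ("protein", "water", "organic", "ion"):
        return atoms.role == tok, pos + 1
    raise SelectionError(f"unknown selection keyword {tok!r}")


def select(atoms: AtomTable, expression: str) -> np.ndarray:
    """Resolve a selection expression to sorted, duplicate-free atom indices.

    Grammar: whitespace-separated terms joined by ``and`` (intersection,
    implicit between adjacent terms).  Terms: ``backbone``, ``water_oxygen``,
    ``protein``, ``water``, ``organic``, ``ion``, ``catalytic``, ``all``,
    ``resid N`` / ``resid N:M``.
    """
    tokens = expression.strip().lower().split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = np.ones(len(atoms), dtype=bool)
    pos = 0
    while pos < len(tokens):
        if tokens[pos] == "and":
            pos += 1
            continue
        term, pos = _term_mask(atoms, tokens, pos)
        mask &= term
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return idx
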