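import numpy as np
import pytest

from maostraj.model import Trajectory


def _pdb_line(record, serial, name, resname, resid, x, y, z, element):
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} A{resid:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """3-residue SER-LEU-GLY peptide plus a water and an n-heptane carbon."""
    lines = []
    serial = 1
    residues = [
        ("SER", 1, [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("OG", "O")]),
        ("LEU", 2, [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]),
        ("GLY", 3, [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]),
    ]
    x = 0.0
    for resname, resid, atoms in residues:
        for i, (name, el) in enumerate(atoms):
            lines.append(_pdb_line("ATOM", serial, name, resname, resid, x + 1.3 * i, 0.4 * i, 0.2 * i, el))
            serial += 1
        x += 4.0
    lines.append(_pdb_line("HETATM", serial, "O", "HOH", 4, 20.0, 5.0, 5.0, "O"))
    serial += 1
    lines.append(_pdb_line("HETATM", serial, "C1", "HEP", 5, 25.0, 5.0, 5.0, "C"))
    lines.append("END\n")
    path = tmp_path / "toy.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def peptide_trajectory():
    """Deterministic 2-frame trajectory of 4 non-collinear atoms."""
    frame0 = np.array(
        [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0], [0.0, 0.0, 1.5]]
    )
    frame1 = frame0.copy()
    frame1[3, 0] += 0.4
    coords = np.stack([frame0, frame1]) + 10.0
    return Trajectory(coords, np.array([0.0, 1.0]), np.array([50.0, 50.0, 50.0]))


def rotation_z(angle_deg):
    a = np.radians(angle_deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
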