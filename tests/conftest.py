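"""Shared helpers: hand-built receptors, minimal ligands, feature-set factories."""
from __future__ import annotations

import numpy as np
import pytest

from nasift.chem_perception import Donor, FeatureAtom, FeatureSet, Ring
from nasift.config import GeometryConfig
from nasift.fixtures import _nucleotide_coords  # first-class generator internals
from nasift.geometry import ring_geometry
from nasift.model_io import Atom, Receptor, Residue, parse_ligands, write_receptor_pdb


@pytest.fixture
def cfg() -> GeometryConfig:
    return GeometryConfig()


def build_receptor(letters, spacing=14.0, chains=None, numbers=None,
                   waters=(), ions=()) -> Receptor:
    """Receptor of idealized nucleotides spaced ``spacing`` A apart on x."""
    chains = chains or ["A"] * len(letters)
    numbers = numbers or list(range(1, len(letters) + 1))
    residues = []
    serial = 0
    for i, (letter, chain, number) in enumerate(zip(letters, chains, numbers)):
        coords = _nucleotide_coords(letter)
        atoms = []
        for name, xyz in coords.items():
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              coords=(xyz[0] + spacing * i, xyz[1], xyz[2])))
        residues.append(Residue(chain=chain, number=number, name=letter, atoms=atoms))
    water_atoms = [Atom(serial=9000 + i, name="O", element="O", coords=tuple(w))
                   for i, w in enumerate(waters, 1)]
    ion_atoms = [Atom(serial=9500 + i, name=el, element=el, coords=tuple(xyz))
                 for i, (el, xyz) in enumerate(ions, 1)]
    return Receptor(residues=residues, waters=water_atoms, ions=ion_atoms)


def receptor_pdb(letters, **kwargs) -> str:
    return write_receptor_pdb(build_receptor(letters, **kwargs))


def sdf_record(molblock_atoms, bonds, charges=(), title="probe") -> str:
    """Tiny V2000 writer for hand-specified test molecules.

    molblock_atoms: list of (symbol, (x, y, z)); bonds: (i, j, order) 1-based
    in the output but given 0-based here; charges: (atom_index, charge).
    """
    lines = [title, "  test  3D", ""]
    lines.append(f"{len(molblock_atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for symbol, (x, y, z) in molblock_atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {symbol:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
    if charges:
        entries = "".join(f"{i + 1:4d}{c:4d}" for i, c in charges)
        lines.append(f"M  CHG{len(charges):3d}{entries}")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def ligand_from(molblock_atoms, bonds, charges=(), title="probe"):
    return parse_ligands(sdf_record(molblock_atoms, bonds, charges, title))[0]


# --- feature-set factories for detector unit tests -------------------------


def fa(label, coords, element="O", neighbors=()):
    return FeatureAtom(label=label, index=0, element=element,
                       coords=tuple(map(float, coords)),
                       neighbors=tuple(tuple(map(float, n)) for n in neighbors))


def donor(label, coords, h_coords=None, element="N"):
    hs = () if h_coords is None else (fa(label + "_H", h_coords, "H"),)
    return Donor(heavy=fa(label, coords, element), hydrogens=hs)


def hexagon_ring(label, centroid, normal, side=1.39):
    centroid = np.asarray(centroid, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, normal)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    verts = [centroid + side * (np.cos(np.radians(60 * k)) * e1
                                + np.sin(np.radians(60 * k)) * e2)
             for k in range(6)]
    c, n = ring_geometry(verts)
    return Ring(members=tuple(f"{label}_{k}" for k in range(6)),
                centroid=tuple(c), normal=tuple(n))


def feature_set(**kwargs) -> FeatureSet:
    return FeatureSet(**kwargs)
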