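"""Synthetic probe complexes with exactly specified interaction geometry.

Every detector and pipeline stage is testable without any external structure:
:func:`make_probe_complex` emits a (PDB text, SDF text) pair in which a
hand-built nucleotide receptor and a minimal functional-group ligand
(methanol, ammonium, benzene, chlorobenzene, acetate, methane) realize one
requested interaction at an exact distance/angle/offset.

The emitted pair is expressed in a canonical frame: the receptor anchor atom
(or ring centroid) sits at the origin and the approach direction is +x, so
the defining distance survives the fixed-precision PDB/SDF coordinate fields
exactly for atom-anchored probes (ring-centroid anchors are exact to the
1e-3 A PDB precision).  All randomness (small jitter on decoy atoms) is
controlled by the seed; identical spec + seed gives byte-identical files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .detectors import FIXED_CHANNELS
from .errors import SpecError
from .model_io import Atom, Receptor, Residue, write_receptor_pdb

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

_TEMPLATES = ("A", "C", "G", "U", "dinucleotide")

_DEFAULT_MEDIATOR = {"Mg_mediated": "MG", "K_mediated": "K", "Na_mediated": "NA",
                     "OtherMetal_mediated": "ZN", "Water_mediated": "HOH"}


@dataclass(frozen=True)
class ProbeSpec:
    """Request for one synthetic complex realizing a given interaction."""
    itype: str
    distance: float
    angle: float | None = None
    offset: float | None = None
    mediator: str | None = None          # None -> channel default; "" -> forbid
    receptor_template: str = "G"

    def __post_init__(self):
        if self.distance <= 0:
            raise SpecError("probe distance must be positive")
        if self.angle is not None and not 0.0 <= self.angle <= 180.0:
            raise SpecError("probe angle must lie in [0, 180] degrees")
        if self.offset is not None and self.offset < 0:
            raise SpecError("probe offset must be non-negative")
        if self.receptor_template not in _TEMPLATES:
            raise SpecError(f"unknown receptor template {self.receptor_template!r}")
        known = set(FIXED_CHANNELS) | {"Contact"}
        if self.itype not in known:
            raise SpecError(f"unknown probe interaction type {self.itype!r}")
        if self.itype in _DEFAULT_MEDIATOR and self.mediator == "":
            raise SpecError(f"{self.itype} probes need a mediator particle")


# ---------------------------------------------------------------------------
# nucleotide construction
# ---------------------------------------------------------------------------


def _rot2d(p, deg):
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])


def _walk_polygon(a, b, n, side, away_from):
    """Remaining n-2 vertices of a regular n-gon built on edge a-b, placed on
    the side opposite ``away_from``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    turn = 360.0 / n
    for sign in (+1.0, -1.0):
        verts = [a, b]
        d = (b - a) / np.linalg.norm(b - a)
        for _ in range(n - 2):
            d = _rot2d(d, sign * turn)
            verts.append(verts[-1] + side * d)
        centroid = np.mean(verts, axis=0)
        if np.linalg.norm(centroid - away_from) > np.linalg.norm(
                np.mean([a, b], axis=0) - away_from):
            return verts[2:]
    raise SpecError("cannot orient fused ring")  # pragma: no cover


_PURINE_HEX = ("N1", "C2", "N3", "C4", "C5", "C6")
_PYRIMIDINE_HEX = ("N1", "C2", "N3", "C4", "C5", "C6")
_EXOCYCLIC = {
    "G": [("C6", "O6", 1.23), ("C2", "N2", 1.35)],
    "A": [("C6", "N6", 1.35)],
    "C": [("C2", "O2", 1.23), ("C4", "N4", 1.35)],
    "U": [("C2", "O2", 1.23), ("C4", "O4", 1.23)],
}


def _base_coords(letter: str) -> dict[str, np.ndarray]:
    side = 1.39
    coords: dict[str, np.ndarray] = {}
    hexagon = [side * np.array([math.cos(math.radians(90 - 60 * k)),
                                math.sin(math.radians(90 - 60 * k))])
               for k in range(6)]
    names = _PURINE_HEX if letter in ("A", "G") else _PYRIMIDINE_HEX
    for name, p in zip(names, hexagon):
        coords[name] = p
    hex_centroid = np.mean(hexagon, axis=0)
    if letter in ("A", "G"):
        # pentagon order C5-C4-N9-C8-N7 closes back onto C5
        n9, c8, n7 = _walk_polygon(coords["C5"], coords["C4"], 5, side, hex_centroid)
        coords["N7"], coords["C8"], coords["N9"] = n7, c8, n9
    for parent, child, length in _EXOCYCLIC[letter]:
        ring = [coords[n] for n in names]
        centroid = np.mean(ring, axis=0)
        d = coords[parent] - centroid
        coords[child] = coords[parent] + length * d / np.linalg.norm(d)
    return {k: np.array([v[0], v[1], 0.0]) for k, v in coords.items()}


def _nucleotide_coords(letter: str) -> dict[str, np.ndarray]:
    """Idealized single nucleotide (full 5'-phosphate, canonical atom names)."""
    coords = _base_coords(letter)
    attach = "N9" if letter in ("A", "G") else "N1"
    ring_names = list(_PURINE_HEX) + (["N7", "C8", "N9"] if letter in ("A", "G") else [])
    bicyclic_centroid = np.mean([coords[n] for n in ring_names], axis=0)
    out = coords[attach] - bicyclic_centroid
    out = out / np.linalg.norm(out)

    c1 = coords[attach] + 1.47 * out
    e1, e2 = out, _Z
    R = 1.52 / (2.0 * math.sin(math.pi / 5.0))
    cs = c1 + R * e1
    sugar_names = ("C1'", "C2'", "C3'", "C4'", "O4'")
    for k, name in enumerate(sugar_names):
        ang = math.radians(180.0 + 72.0 * k)
        coords[name] = cs + R * (math.cos(ang) * e1 + math.sin(ang) * e2)

    def radial(p, length):
        d = p - cs
        return p + length * d / np.linalg.norm(d)

    coords["O2'"] = radial(coords["C2'"], 1.41)
    coords["O3'"] = radial(coords["C3'"], 1.41)
    coords["C5'"] = radial(coords["C4'"], 1.52)
    coords["O5'"] = radial(coords["C5'"], 1.42)
    w = coords["O5'"] - coords["C5'"]
    w = w / np.linalg.norm(w)
    coords["P"] = coords["O5'"] + 1.61 * w
    p1 = np.cross(w, e2)
    if np.linalg.norm(p1) < 1e-6:
        p1 = np.cross(w, e1)
    p1 = p1 / np.linalg.norm(p1)
    for name, v in (("OP1", w + p1), ("OP2", w - p1)):
        coords[name] = coords["P"] + 1.48 * v / np.linalg.norm(v)
    return coords


def _build_receptor(template: str, transform, waters=(), ions=()) -> Receptor:
    """Assemble Residue/Receptor objects from template coords, applying the
    canonical-frame transform; waters/ions are (element, xyz) extras."""
    letters = ["G", "A"] if template == "dinucleotide" else [template]
    residues = []
    serial = 0
    for i, letter in enumerate(letters):
        shift = np.array([8.5 * i, 0.0, 0.0])
        coords = _nucleotide_coords(letter)
        atoms = []
        for name, xyz in coords.items():
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              coords=tuple(transform(xyz + shift))))
        residues.append(Residue(chain="A", number=i + 1, name=letter, atoms=atoms))
    water_atoms = [Atom(serial=9000 + i, name="O", element="O", coords=tuple(map(float, xyz)))
                   for i, (_el, xyz) in enumerate(waters, 1)]
    ion_atoms = [Atom(serial=9500 + i, name=el, element=el, coords=tuple(map(float, xyz)))
                 for i, (el, xyz) in enumerate(ions, 1)]
    return Receptor(residues=residues, waters=water_atoms, ions=ion_atoms,
                    source_path="<probe>")


def _frame_transform(anchor: np.ndarray, primary: np.ndarray, secondary: np.ndarray):
    """Map anchor -> origin, primary -> +x, secondary into the xz half-plane."""
    x = primary / np.linalg.norm(primary)
    z = secondary - np.dot(secondary, x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        z = _Z - np.dot(_Z, x) * x
        if np.linalg.norm(z) < 1e-9:
            z = _Y - np.dot(_Y, x) * x
        nz = np.linalg.norm(z)
    z = z / nz
    y = np.cross(z, x)
    M = np.vstack([x, y, z])

    def transform(p):
        return M @ (np.asarray(p, float) - anchor)

    return transform


# ---------------------------------------------------------------------------
# ligand probes (RDKit molecules in the canonical frame)
# ---------------------------------------------------------------------------


def _mol_from_atoms(name, atoms, bonds):
    """atoms: (symbol, charge, xyz); bonds: (i, j, order with 1/2)."""
    em = Chem.RWMol()
    for symbol, charge, _xyz in atoms:
        a = Chem.Atom(symbol)
        a.SetFormalCharge(charge)
        em.AddAtom(a)
    for i, j, order in bonds:
        em.AddBond(i, j, Chem.BondType.DOUBLE if order == 2 else Chem.BondType.SINGLE)
    mol = em.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (_s, _c, xyz) in enumerate(atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    mol.SetProp("_Name", name)
    return mol


def _sdf_text(mol) -> str:
    return Chem.MolToMolBlock(mol, kekulize=True) + "$$$$\n"


def _hexagon_3d(centroid, normal, start_dir, side=1.39):
    e1 = start_dir - np.dot(start_dir, normal) * normal
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return [centroid + side * (math.cos(math.radians(60 * k)) * e1
                               + math.sin(math.radians(60 * k)) * e2)
            for k in range(6)]


def _benzene(name, centroid, normal, start_dir=_Y):
    verts = _hexagon_3d(np.asarray(centroid, float), np.asarray(normal, float),
                        np.asarray(start_dir, float))
    atoms = [("C", 0, v) for v in verts]
    bonds = [(k, (k + 1) % 6, 2 if k % 2 == 0 else 1) for k in range(6)]
    return _mol_from_atoms(name, atoms, bonds)


def _ammonium(pos, jitter):
    pos = np.asarray(pos, float)
    hs = [pos + 1.03 * np.array(v) / math.sqrt(3.0)
          for v in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]
    atoms = [("N", 1, pos)] + [("H", 0, h + jitter(h)) for h in hs]
    bonds = [(0, k, 1) for k in range(1, 5)]
    return _mol_from_atoms("ammonium", atoms, bonds)


def _methanol(o_pos, toward_receptor, h_angle=None, jitter=None):
    """Methanol with its hydroxyl O at o_pos; if h_angle is given, the O-H
    hydrogen is placed so that angle(O, H, acceptor) equals it, with the
    acceptor at the origin and o_pos on the +x axis."""
    o = np.asarray(o_pos, float)
    u = np.asarray(toward_receptor, float)
    u = u / np.linalg.norm(u)
    # carbon placed behind the oxygen, tilted out of the O...A axis
    c_dir = -u * math.cos(math.radians(71.0)) + _Z * math.sin(math.radians(71.0))
    c = o + 1.43 * c_dir
    if jitter is not None:
        c = c + jitter(c)
    atoms = [("O", 0, o), ("C", 0, c)]
    bonds = [(0, 1, 1)]
    if h_angle is not None:
        h = _solve_h_position(o, np.zeros(3), h_angle)
        atoms.append(("H", 0, h))
        bonds.append((0, len(atoms) - 1, 1))
    return _mol_from_atoms("methanol", atoms, bonds)


def _solve_h_position(donor, acceptor, target_angle, bond=1.00):
    """Donor hydrogen at distance ``bond`` from the donor such that the
    D-H...A angle (vertex at H) equals target_angle, by bisection over the
    tilt of the O-H bond in the donor-acceptor plane."""
    d = np.asarray(donor, float)
    a = np.asarray(acceptor, float)
    e = (a - d) / np.linalg.norm(a - d)
    perp = _Z - np.dot(_Z, e) * e
    if np.linalg.norm(perp) < 1e-9:
        perp = _Y - np.dot(_Y, e) * e
    perp = perp / np.linalg.norm(perp)

    def angle_at_h(phi):
        h = d + bond * (math.cos(phi) * e + math.sin(phi) * perp)
        v1 = d - h
        v2 = a - h
        cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))

    lo, hi = 0.0, math.pi  # angle_at_h(0) = 180, decreasing toward ~0
    if not angle_at_h(lo) >= target_angle >= angle_at_h(hi):
        raise SpecError(f"D-H...A angle {target_angle} not realizable")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if angle_at_h(mid) >= target_angle:
            lo = mid
        else:
            hi = mid
    phi = 0.5 * (lo + hi)
    return d + bond * (math.cos(phi) * e + math.sin(phi) * perp)


def _acetate(o_pos, away=_X):
    o = np.asarray(o_pos, float)
    away = np.asarray(away, float) / np.linalg.norm(away)
    c = o + 1.26 * away
    o2 = c + 1.23 * _rotate_about(_Y, away, 120.0)
    ch3 = c + 1.50 * _rotate_about(_Y, away, -120.0)
    atoms = [("O", -1, o), ("C", 0, c), ("O", 0, o2), ("C", 0, ch3)]
    bonds = [(0, 1, 1), (1, 2, 2), (1, 3, 1)]
    return _mol_from_atoms("acetate", atoms, bonds)


def _rotate_about(axis, v, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    v = np.asarray(v, float)
    r = math.radians(deg)
    return (v * math.cos(r) + np.cross(axis, v) * math.sin(r)
            + axis * np.dot(axis, v) * (1 - math.cos(r)))


def _methane(pos, jitter=None):
    return _mol_from_atoms("methane", [("C", 0, np.asarray(pos, float))], [])


def _chlorobenzene(cl_pos, c_pos):
    """Chlorobenzene with Cl at cl_pos and the attached ring carbon at c_pos."""
    cl = np.asarray(cl_pos, float)
    c1 = np.asarray(c_pos, float)
    away = (c1 - cl) / np.linalg.norm(c1 - cl)
    centroid = c1 + 1.39 * away
    normal = np.cross(away, _Y)
    if np.linalg.norm(normal) < 1e-6:
        normal = np.cross(away, _Z)
    normal = normal / np.linalg.norm(normal)
    verts = _hexagon_3d(centroid, normal, start_dir=-away)
    atoms = [("C", 0, v) for v in verts] + [("Cl", 0, cl)]
    bonds = [(k, (k + 1) % 6, 2 if k % 2 == 0 else 1) for k in range(6)] + [(0, 6, 1)]
    return _mol_from_atoms("chlorobenzene", atoms, bonds)


# ---------------------------------------------------------------------------
# probe assembly
# ---------------------------------------------------------------------------

#: receptor anchor atoms per template letter: (H-bond partner, anion, halogen
#: acceptor with single heavy neighbor Y)
_HB_ANCHOR = {"G": "N7", "A": "N7", "C": "O2", "U": "O2"}
_HAL_ANCHOR = {"G": ("O6", "C6"), "A": ("N7", "C8"), "C": ("O2", "C2"), "U": ("O2", "C2")}


def make_probe_complex(spec: ProbeSpec, seed: int = 0) -> tuple[str, str]:
    """Emit (pdb_text, sdf_text) realizing the requested interaction geometry."""
    rng = np.random.default_rng(seed)

    def jitter(_p):
        return rng.normal(0.0, 0.02, 3)

    letter = "G" if spec.receptor_template == "dinucleotide" else spec.receptor_template
    coords = _nucleotide_coords(letter)
    ring_names = list(_PURINE_HEX) if letter in ("A", "G") else list(_PYRIMIDINE_HEX)
    hex_centroid = np.mean([coords[n] for n in ring_names], axis=0)
    d = spec.distance
    waters: list[tuple[str, np.ndarray]] = []
    ions: list[tuple[str, np.ndarray]] = []

    it = spec.itype
    if it in ("HB", "Contact"):
        anchor_name = _HB_ANCHOR[letter]
        anchor = coords[anchor_name]
        primary = anchor - hex_centroid
        transform = _frame_transform(anchor, primary, _Z)
        if it == "HB":
            angle = spec.angle  # None -> distance-only probe without explicit H
            mol = _methanol(np.array([d, 0.0, 0.0]), toward_receptor=-_X,
                            h_angle=angle, jitter=jitter)
        else:
            mol = _methane(np.array([d, 0.0, 0.0]))
    elif it == "Lipophilic":
        anchor = coords["C5'"]
        sugar_centroid = np.mean([coords[n] for n in ("C1'", "C2'", "C3'", "C4'", "O4'")],
                                 axis=0)
        transform = _frame_transform(anchor, anchor - sugar_centroid, _Z)
        mol = _methane(np.array([d, 0.0, 0.0]))
    elif it == "HAL":
        acc_name, y_name = _HAL_ANCHOR[letter]
        anchor = coords[acc_name]
        y = coords[y_name]
        acc_angle = 120.0
        don_angle = spec.angle if spec.angle is not None else 165.0
        # X goes on +x; the frame is chosen so that angle(X...A-Y) = acc_angle
        transform = _frame_transform(anchor, _rotate_about(_Z, y - anchor, -acc_angle),
                                     y - anchor)
        x_pos = np.array([d, 0.0, 0.0])
        # C so that angle(C-X...A) = don_angle, with A at the origin
        c_dir = _rotate_about(_Y, _X, 180.0 - don_angle)
        c_pos = x_pos + 1.77 * c_dir
        mol = _chlorobenzene(x_pos, c_pos)
    elif it == "CationAnion":
        anchor = coords["OP1"]
        transform = _frame_transform(anchor, anchor - coords["P"], _Z)
        mol = _ammonium(np.array([d, 0.0, 0.0]), jitter)
    elif it in ("PiCation", "PiAnion"):
        anchor = hex_centroid
        transform = _frame_transform(anchor, _Z, _X)  # ring normal becomes +x
        alpha = math.radians(spec.angle or 0.0)
        pos = np.array([d * math.cos(alpha), 0.0, d * math.sin(alpha)])
        if it == "PiCation":
            mol = _ammonium(pos, jitter)
        else:
            mol = _acetate(pos, away=_X)
    elif it == "PiStacking":
        anchor = hex_centroid
        transform = _frame_transform(anchor, _Z, _X)
        offset = spec.offset or 0.0
        if offset > d + 1e-12:
            raise SpecError("stacking offset cannot exceed the centroid distance")
        h = math.sqrt(d * d - offset * offset)
        centroid = np.array([h, 0.0, offset])
        tilt = spec.angle or 0.0
        normal = _rotate_about(_Y, _X, tilt)
        mol = _benzene("benzene", centroid, normal, start_dir=_Z)
    elif it in ("Mg_mediated", "K_mediated", "Na_mediated", "OtherMetal_mediated",
                "Water_mediated"):
        mediator = spec.mediator or _DEFAULT_MEDIATOR[it]
        if it == "Water_mediated":
            anchor = coords[_HB_ANCHOR[letter]]
            primary = anchor - hex_centroid
        else:
            anchor = coords["OP1"]
            primary = anchor - coords["P"]
        transform = _frame_transform(anchor, primary, _Z)
        bridge = np.array([d, 0.0, 0.0])
        if it == "Water_mediated":
            if mediator != "HOH":
                raise SpecError("water-mediated probes use a HOH mediator")
            waters.append(("HOH", bridge))
        else:
            ions.append((mediator.upper(), bridge))
        mol = _methanol(np.array([2.0 * d, 0.0, 0.0]), toward_receptor=-_X,
                        h_angle=None, jitter=jitter)
    else:  # pragma: no cover - guarded by ProbeSpec
        raise SpecError(f"unsupported probe type {it!r}")

    receptor = _build_receptor(spec.receptor_template, transform,
                               waters=waters, ions=ions)
    return write_receptor_pdb(receptor), _sdf_text(mol)


# ---------------------------------------------------------------------------
# random populations (similarity / wrapper / oracle testing)
# ---------------------------------------------------------------------------


def make_fingerprint_population(n: int, density: float, length: int,
                                seed: int = 0) -> list[np.ndarray]:
    """n independent Bernoulli(density) bit vectors of the given length."""
    if not 0.0 <= density <= 1.0:
        raise SpecError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return [(rng.random(length) < density).astype(np.uint8) for _ in range(n)]


@dataclass
class FeatureScene:
    """Randomized feature sets for one synthetic residue-ligand encounter."""
    residue_features: object
    ligand_features: object
    waters: list
    ions: list
    residue_key: tuple[str, int, str] = ("A", 1, "G")


def random_feature_scene(seed: int, n_per_class: int = 3, box: float = 9.0,
                         with_hydrogens: bool = True) -> FeatureScene:
    """Random feature sets whose pair distances straddle every default cutoff.

    Used for detector stress-testing against brute-force predicate oracles:
    coordinates are uniform in a ``box``-angstrom cube, which at the default
    cutoffs yields a healthy mixture of firing and non-firing pairs for all
    twelve channels.
    """
    from .chem_perception import Donor, FeatureAtom, FeatureSet, Ring
    from .geometry import ring_geometry

    rng = np.random.default_rng(seed)

    def pt():
        return rng.uniform(0.0, box, 3)

    def unit():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def fa(prefix, i, element, coords, neighbors=()):
        return FeatureAtom(label=f"{prefix}{i}", index=i, element=element,
                           coords=tuple(coords),
                           neighbors=tuple(tuple(n) for n in neighbors))

    def random_ring(prefix, i):
        centroid = pt()
        normal = unit()
        e1 = np.cross(normal, unit())
        while np.linalg.norm(e1) < 1e-6:  # pragma: no cover - vanishing cross product
            e1 = np.cross(normal, unit())
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        verts = [centroid + 1.39 * (math.cos(math.radians(60 * k)) * e1
                                    + math.sin(math.radians(60 * k)) * e2)
                 for k in range(6)]
        c, nrm = ring_geometry(verts)
        return Ring(members=tuple(f"{prefix}R{i}_{k}" for k in range(6)),
                    centroid=tuple(c), normal=tuple(nrm))

    def side(prefix, with_halogens):
        fs = FeatureSet()
        for i in range(n_per_class):
            heavy = fa(f"{prefix}D", i, "N", pt())
            hs = ()
            if with_hydrogens:
                hs = (fa(f"{prefix}DH", i, "H", heavy.xyz + unit()),)
            fs.hb_donors.append(Donor(heavy=heavy, hydrogens=hs))
            p = pt()
            fs.hb_acceptors.append(fa(f"{prefix}A", i, "O", p, neighbors=(p + 1.4 * unit(),)))
            fs.cations.append(fa(f"{prefix}C+", i, "N", pt()))
            fs.anions.append(fa(f"{prefix}C-", i, "O", pt()))
            fs.lipophilic.append(fa(f"{prefix}L", i, "C", pt()))
            fs.rings.append(random_ring(prefix, i))
            if with_halogens:
                c = pt()
                x = c + 1.77 * unit()
                fs.halogen_donors.append((fa(f"{prefix}XC", i, "C", c), fa(f"{prefix}X", i, "CL", x)))
        # donors double as acceptor-capable N; acceptors as coordination partners
        return fs

    waters = [fa("W", i, "O", pt()) for i in range(n_per_class)]
    elements = ["MG", "K", "NA", "ZN", "CA"]
    picks = [elements[rng.integers(len(elements))] for _ in range(n_per_class)]
    ions = [fa(f"{el}@", i, el, pt()) for i, el in enumerate(picks)]
    return FeatureScene(residue_features=side("r", with_halogens=False),
                        ligand_features=side("l", with_halogens=True),
                        waters=waters, ions=ions)
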