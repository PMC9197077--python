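"""Perception of interaction-capable features on receptor residues and ligands.

Every feature class (hydrogen-bond donors and acceptors, halogen-bond donors,
charged centers, aromatic rings, lipophilic atoms) is defined by a SMARTS
pattern collected in :class:`PerceptionRules`, so the same matching machinery
serves the built-in detectors, user overrides, and the plugin system.
Receptor residues are first converted to RDKit molecules using the canonical
nucleotide templates (PDB files carry no bond orders), after which perception
is identical for both sides — with two receptor-specific rules: the phosphate
oxygens OP1/OP2(/OP3) are always treated as anions regardless of recorded
charges, and every receptor carbon counts as a lipophilic contact site (the
strict "C/S bonded only to C,H,S,halogen" rule would leave a canonical
nucleotide with no lipophilic atoms at all, contradicting the observed
dominance of nucleobase/ribose carbons in lipophilic contacts).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from . import templates
from .errors import GeometryError, PatternError, UnsupportedResidueError
from .geometry import ring_geometry
from .model_io import LigandRecord, Residue

# ---------------------------------------------------------------------------
# feature containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureAtom:
    """One perceived atom: label (PDB name or element+index), coordinates and
    the coordinates of its heavy neighbors (needed for angle criteria)."""
    label: str
    index: int
    element: str
    coords: tuple[float, float, float]
    neighbors: tuple[tuple[float, float, float], ...] = ()

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, float)


@dataclass(frozen=True)
class Ring:
    """Aromatic ring: ordered member labels, centroid and unit plane normal."""
    members: tuple[str, ...]
    centroid: tuple[float, float, float]
    normal: tuple[float, float, float]

    @property
    def label(self) -> str:
        return "ring(" + ",".join(self.members) + ")"

    @property
    def centroid_xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, float)

    @property
    def normal_xyz(self) -> np.ndarray:
        return np.asarray(self.normal, float)


@dataclass(frozen=True)
class Donor:
    heavy: FeatureAtom
    hydrogens: tuple[FeatureAtom, ...] = ()


@dataclass
class FeatureSet:
    """All interaction-capable features of one residue or one ligand record."""
    hb_donors: list[Donor] = field(default_factory=list)
    hb_acceptors: list[FeatureAtom] = field(default_factory=list)
    halogen_donors: list[tuple[FeatureAtom, FeatureAtom]] = field(default_factory=list)
    cations: list[FeatureAtom] = field(default_factory=list)
    anions: list[FeatureAtom] = field(default_factory=list)
    rings: list[Ring] = field(default_factory=list)
    lipophilic: list[FeatureAtom] = field(default_factory=list)
    heavy_atoms: list[FeatureAtom] = field(default_factory=list)


# ---------------------------------------------------------------------------
# SMARTS rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerceptionRules:
    """SMARTS definitions of the perceived feature classes (user-overridable).

    The donor/acceptor typing follows common interaction-profiler practice:
    donors are N/O/S bearing at least one hydrogen (explicit or implicit);
    acceptors are N/O with an available lone pair, excluding positively
    charged and quaternary nitrogen, pyrrole-type aromatic NH, amide nitrogen
    and aryl-conjugated amines.  Fluorine is excluded from halogen-bond
    donors (negligible sigma-hole); Cl/Br/I are included.
    """
    donor_smarts: str = "[#7,#8,#16;!H0]"
    acceptor_smarts: str = ("[$([O;X1;!+]),$([O;X2;!+]),$([n;X2]),$([N;X1]),"
                            "$([N;X2;!+]),$([N;X3;!+;!$([N][C,S]=[O,N,S]);!$([N]-a)])]")
    halogen_donor_smarts: str = "[#6][Cl,Br,I;X1]"
    lipophilic_smarts: str = "[#6,#16;+0;!$([#6,#16]~[!#6;!#1;!#16;!F;!Cl;!Br;!I])]"
    ring_sizes: tuple[int, ...] = (5, 6)


DEFAULT_RULES = PerceptionRules()


def compile_smarts(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise PatternError(f"invalid SMARTS: {pattern!r}")
    return query


def match_smarts(molecule, pattern: str) -> list[tuple[int, ...]]:
    """All unique SMARTS matches on a residue/ligand/Mol, sorted deterministically."""
    mol = as_mol(molecule)
    query = compile_smarts(pattern)
    matches = mol.GetSubstructMatches(query, uniquify=True)
    return sorted(tuple(m) for m in matches)


# ---------------------------------------------------------------------------
# residue -> RDKit molecule
# ---------------------------------------------------------------------------

_SOFT_SANITIZE = (Chem.SanitizeFlags.SANITIZE_ALL
                  ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
                  ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)


def residue_to_mol(residue: Residue, o3_bridged: bool = False) -> Chem.Mol:
    """Build an RDKit molecule for one nucleotide from the canonical template.

    Bonds are taken from the kekule template for the residue's (best-match)
    base letter; explicit hydrogens are attached to their nearest heavy atom.
    ``o3_bridged`` marks an O3' that is esterified to the next residue's
    phosphate, suppressing the spurious implicit hydrogen a lone residue
    would otherwise get there.  Atom order equals ``residue.atoms`` order.
    """
    letter = residue.template_letter
    bond_table = templates.residue_bonds(letter)
    emol = Chem.RWMol()
    idx_of: dict[str, int] = {}
    for i, atom in enumerate(residue.atoms):
        ratom = Chem.Atom(atom.element.capitalize())
        charge = atom.formal_charge or templates.TEMPLATE_CHARGES.get(atom.name, 0)
        ratom.SetFormalCharge(charge)
        ratom.SetNoImplicit(atom.is_hydrogen)
        emol.AddAtom(ratom)
        if not atom.is_hydrogen:
            idx_of[atom.name] = i

    for a, b, order in bond_table:
        if a in idx_of and b in idx_of:
            emol.AddBond(idx_of[a], idx_of[b],
                         Chem.BondType.DOUBLE if order == 2 else Chem.BondType.SINGLE)

    heavies = [(i, a) for i, a in enumerate(residue.atoms) if not a.is_hydrogen]
    for i, atom in enumerate(residue.atoms):
        if atom.is_hydrogen:
            if not heavies:
                raise UnsupportedResidueError("residue consists of hydrogens only")
            j, _ = min(heavies, key=lambda ha: np.linalg.norm(ha[1].xyz - atom.xyz))
            emol.AddBond(i, j, Chem.BondType.SINGLE)

    if o3_bridged and "O3'" in idx_of:
        emol.GetAtomWithIdx(idx_of["O3'"]).SetNoImplicit(True)

    mol = emol.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, atom in enumerate(residue.atoms):
        conf.SetAtomPosition(i, Point3D(*atom.coords))
    mol.AddConformer(conf)
    try:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(mol, _SOFT_SANITIZE)
    except Exception as exc:
        raise UnsupportedResidueError(
            f"residue {residue.name} {residue.number} cannot be sanitized: {exc}") from exc
    return mol


def as_mol(molecule) -> Chem.Mol:
    """Coerce a Residue / LigandRecord / Chem.Mol to an RDKit molecule."""
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, LigandRecord):
        return molecule.mol
    if isinstance(molecule, Residue):
        cached = getattr(molecule, "_mol", None)
        if cached is None:
            cached = residue_to_mol(molecule)
            molecule._mol = cached
        return cached
    raise TypeError(f"cannot interpret {type(molecule).__name__} as a molecule")


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------


def _labels_for(molecule, mol: Chem.Mol) -> list[str]:
    if isinstance(molecule, Residue):
        return [a.name for a in molecule.atoms]
    return [f"{a.GetSymbol()}{a.GetIdx() + 1}" for a in mol.GetAtoms()]


def _feature_atom(mol: Chem.Mol, conf, labels, idx: int) -> FeatureAtom:
    a = mol.GetAtomWithIdx(idx)
    p = conf.GetAtomPosition(idx)
    neighbors = []
    for nb in a.GetNeighbors():
        if nb.GetAtomicNum() > 1:
            q = conf.GetAtomPosition(nb.GetIdx())
            neighbors.append((q.x, q.y, q.z))
    return FeatureAtom(label=labels[idx], index=idx, element=a.GetSymbol().upper(),
                       coords=(p.x, p.y, p.z), neighbors=tuple(neighbors))


def perceive_features(molecule, role: str = "ligand",
                      rules: PerceptionRules = DEFAULT_RULES) -> FeatureSet:
    """Perceive all interaction features of a residue or ligand record.

    ``role`` is ``"receptor_residue"`` or ``"ligand"``; it switches on the
    two receptor-specific rules (forced OP1/OP2/OP3 anions, all-carbon
    lipophilicity).  Empty feature sets are valid results.
    """
    if role not in ("receptor_residue", "ligand"):
        raise ValueError(f"unknown role {role!r}")
    mol = as_mol(molecule)
    conf = mol.GetConformer()
    labels = _labels_for(molecule, mol)
    fs = FeatureSet()

    def fa(idx: int) -> FeatureAtom:
        return _feature_atom(mol, conf, labels, idx)

    for a in mol.GetAtoms():
        if a.GetAtomicNum() > 1:
            fs.heavy_atoms.append(fa(a.GetIdx()))

    # donors, with their explicit hydrogens (implicit-H donors have an empty
    # hydrogen tuple and trigger MissingHydrogenError only in D-H...A mode)
    for (idx,) in mol.GetSubstructMatches(compile_smarts(rules.donor_smarts)):
        heavy = fa(idx)
        hs = []
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetAtomicNum() == 1:
                hs.append(fa(nb.GetIdx()))
        fs.hb_donors.append(Donor(heavy=heavy, hydrogens=tuple(hs)))

    for (idx,) in mol.GetSubstructMatches(compile_smarts(rules.acceptor_smarts)):
        fs.hb_acceptors.append(fa(idx))

    for c_idx, x_idx in mol.GetSubstructMatches(compile_smarts(rules.halogen_donor_smarts)):
        fs.halogen_donors.append((fa(c_idx), fa(x_idx)))

    metal_nums = {Chem.GetPeriodicTable().GetAtomicNumber(e.capitalize())
                  for e in templates.METAL_SET}
    forced_anions = set()
    if role == "receptor_residue":
        forced_anions = {i for i, lbl in enumerate(labels) if lbl in templates.PHOSPHATE_ANIONS}
    for a in mol.GetAtoms():
        idx = a.GetIdx()
        if a.GetFormalCharge() > 0 or a.GetAtomicNum() in metal_nums:
            fs.cations.append(fa(idx))
        if a.GetFormalCharge() < 0 or idx in forced_anions:
            fs.anions.append(fa(idx))

    ring_info = mol.GetRingInfo()
    for ring_atoms in ring_info.AtomRings():
        if len(ring_atoms) not in rules.ring_sizes:
            continue
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring_atoms):
            continue
        coords = [conf.GetAtomPosition(i) for i in ring_atoms]
        try:
            centroid, normal = ring_geometry([(p.x, p.y, p.z) for p in coords])
        except GeometryError:
            continue
        fs.rings.append(Ring(members=tuple(labels[i] for i in ring_atoms),
                             centroid=tuple(centroid), normal=tuple(normal)))

    if role == "receptor_residue":
        charged = {f.index for f in fs.cations} | {f.index for f in fs.anions}
        for a in mol.GetAtoms():
            if a.GetAtomicNum() == 6 and a.GetIdx() not in charged:
                fs.lipophilic.append(fa(a.GetIdx()))
    else:
        charged = {f.index for f in fs.cations} | {f.index for f in fs.anions}
        for (idx,) in mol.GetSubstructMatches(compile_smarts(rules.lipophilic_smarts)):
            if idx not in charged:
                fs.lipophilic.append(fa(idx))
    return fs


def water_features(oxygen_atoms) -> list[FeatureAtom]:
    """Water oxygens as bare feature atoms (bridge partners for water bridges)."""
    return [FeatureAtom(label=f"HOH{i + 1}", index=a.serial, element="O",
                        coords=tuple(a.coords)) for i, a in enumerate(oxygen_atoms)]


def ion_features(ion_atoms) -> list[FeatureAtom]:
    """Inorganic cations as bare feature atoms (bridge partners / ion ligands)."""
    return [FeatureAtom(label=f"{a.element}@{a.serial}", index=a.serial,
                        element=a.element.upper(), coords=tuple(a.coords))
            for a in ion_atoms]


def shifted(atom: FeatureAtom, delta) -> FeatureAtom:
    """Copy of a feature atom translated by ``delta`` (test/fixture helper)."""
    d = np.asarray(delta, float)
    return replace(atom, coords=tuple(atom.xyz + d),
                   neighbors=tuple(tuple(np.asarray(n) + d) for n in atom.neighbors))
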