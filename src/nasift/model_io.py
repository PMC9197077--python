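"""Receptor PDB and ligand SDF input, and the package's domain model.

The receptor is an RNA or DNA model in PDB format; it may contain water and
inorganic metal cations, which are routed to dedicated lists, but any organic
ligand or buffer molecule must have been removed beforehand (such HETATM
records raise :class:`~nasift.errors.UnsupportedResidueError`).  Ligands come
from a multi-record SDF with protonation states and formal charges already
assigned.

Parsing is delegated to Bio.PDB and RDKit; this module only builds the
light-weight :class:`Atom`/:class:`Residue`/:class:`Receptor`/
:class:`LigandRecord` containers the rest of the package works with.
"""
from __future__ import annotations

import enum
import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from rdkit import Chem
from rdkit import RDLogger

from . import templates
from .errors import (
    ParseError,
    SanitizationError,
    UnclassifiableAtomError,
    UniqueNumberingError,
    UnsupportedResidueError,
)

RDLogger.DisableLog("rdApp.*")

_ATOM_NAME_ALIASES = {"O1P": "OP1", "O2P": "OP2", "O3P": "OP3", "C5M": "C7"}

_BASE_NAME_RE = re.compile(r"^[CNOSP][0-9]+[A-Z0-9']*$")


class Group(enum.Enum):
    PHOSPHATE = "PHOSPHATE"
    SUGAR = "SUGAR"
    BASE = "BASE"


@dataclass(frozen=True)
class Atom:
    """One atom: PDB serial, PDB-style name, element symbol, coordinates (A)."""
    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    formal_charge: int = 0

    def __post_init__(self):
        if not self.element:
            raise ParseError(f"atom {self.name} (serial {self.serial}) has no element")
        if not all(np.isfinite(self.coords)):
            raise ParseError(f"atom {self.name} has non-finite coordinates")
        if not -4 <= self.formal_charge <= 4:
            raise ParseError(f"atom {self.name} formal charge {self.formal_charge} out of range")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, float)


@dataclass
class Residue:
    """One nucleotide with its atoms and the phosphate/sugar/base partition."""
    chain: str
    number: int
    name: str
    atoms: list[Atom]
    group_of: dict[str, Group] = field(default_factory=dict)

    def __post_init__(self):
        if not self.group_of:
            self.group_of = classify_residue_atoms(self)

    @property
    def template_letter(self) -> str:
        letter = templates.best_template(self.name, [a.name for a in self.atoms])
        if letter is None:
            raise UnsupportedResidueError(f"residue {self.name} {self.number} is not a nucleotide")
        return letter

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.name)


@dataclass
class Receptor:
    """Parsed nucleic-acid model: ordered residues plus separated waters/ions."""
    residues: list[Residue]
    waters: list[Atom]
    ions: list[Atom]
    source_path: str = "<memory>"

    def __iter__(self):
        return iter(self.residues)


@dataclass
class LigandRecord:
    """One SDF record; ``pose_index`` is its 1-based position in the file."""
    title: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    pose_index: int
    mol: Chem.Mol | None = None

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ParseError(f"ligand {self.title!r}: bond references missing atom")

    @property
    def ligand_id(self) -> str:
        return f"{self.title or 'ligand'}#{self.pose_index}"


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_residue_atoms(residue: Residue) -> dict[str, Group]:
    """Partition a nucleotide's atom names into PHOSPHATE / SUGAR / BASE.

    P, OP1-3 and the bridging O5'/O3' travel with the phosphate; the ribose
    carbons plus O4'/O2' are SUGAR; every remaining heavy atom with a
    plausible base atom name is BASE.  Hydrogens inherit the group of their
    nearest heavy atom.
    """
    groups: dict[str, Group] = {}
    heavies = [a for a in residue.atoms if not a.is_hydrogen]
    for atom in heavies:
        name = atom.name
        if name in templates.PHOSPHATE_ATOMS:
            groups[name] = Group.PHOSPHATE
        elif name in templates.SUGAR_ATOMS:
            groups[name] = Group.SUGAR
        elif _BASE_NAME_RE.match(name):
            groups[name] = Group.BASE
        else:
            raise UnclassifiableAtomError(
                f"atom {name!r} in residue {residue.name} {residue.number} matches no rule")
    for atom in residue.atoms:
        if atom.is_hydrogen:
            if not heavies:
                raise UnclassifiableAtomError(f"lone hydrogen {atom.name}")
            nearest = min(heavies, key=lambda h: np.linalg.norm(h.xyz - atom.xyz))
            groups[atom.name] = groups[nearest.name]
    return groups


# ---------------------------------------------------------------------------
# receptor parsing
# ---------------------------------------------------------------------------

def _normalize_atom_name(raw: str) -> str:
    name = raw.strip().replace("*", "'")
    return _ATOM_NAME_ALIASES.get(name, name)


def _element_of(bio_atom) -> str:
    el = (bio_atom.element or "").strip().upper()
    if el:
        return el
    stripped = bio_atom.get_name().strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def parse_receptor(pdb_text: str, metal_set: frozenset | set = frozenset(templates.METAL_SET),
                   source_path: str = "<memory>") -> Receptor:
    """Parse a receptor PDB (first MODEL only) into a :class:`Receptor`.

    Waters (HOH/WAT/H2O) are routed to ``waters`` (their oxygen positions),
    single-atom HETATM records with a metal element to ``ions``; any other
    HETATM is treated as an un-removed ligand/buffer and raises.  Residue
    numbers must be unique across the whole structure (all chains).
    """
    if not pdb_text.strip():
        raise ParseError("empty PDB input")
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure("receptor", io.StringIO(pdb_text))
        except Exception as exc:  # Bio.PDB raises assorted exceptions on garbage
            raise ParseError(f"cannot parse PDB: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise ParseError("PDB contains no coordinates")
    model = models[0]  # one model per file; extra MODELs are ignored

    residues: list[Residue] = []
    waters: list[Atom] = []
    ions: list[Atom] = []
    for chain in model:
        chain_residues = []
        for res in chain:
            hetfield, resseq, _icode = res.id
            resname = res.get_resname().strip().upper()
            atoms = [
                Atom(serial=a.serial_number,
                     name=_normalize_atom_name(a.get_name()),
                     element=_element_of(a),
                     coords=tuple(float(x) for x in a.coord))
                for a in res
            ]
            if resname in templates.WATER_NAMES or hetfield == "W":
                waters.extend(a for a in atoms if a.element == "O")
                continue
            heavy = [a for a in atoms if not a.is_hydrogen]
            if len(heavy) == 1 and heavy[0].element in metal_set:
                ions.append(heavy[0])
                continue
            if templates.best_template(resname, [a.name for a in atoms]) is None:
                raise UnsupportedResidueError(
                    f"residue {resname} {resseq} is neither a nucleotide, water, nor a metal ion; "
                    "remove ligands/buffer molecules from the receptor file")
            chain_residues.append(Residue(chain=chain.id.strip() or "A",
                                          number=int(resseq), name=resname, atoms=atoms))
        chain_residues.sort(key=lambda r: r.number)
        residues.extend(chain_residues)

    seen: dict[int, Residue] = {}
    for r in residues:
        if r.number in seen:
            raise UniqueNumberingError(
                f"residue number {r.number} occurs in chain {seen[r.number].chain} "
                f"and chain {r.chain}; receptor numbering must be unique")
        seen[r.number] = r
    if not residues and not waters and not ions:
        raise ParseError("PDB contains no usable records")
    return Receptor(residues=residues, waters=waters, ions=ions, source_path=source_path)


def write_receptor_pdb(receptor: Receptor) -> str:
    """Serialize a receptor back to PDB text (ATOM + water/ion HETATM)."""
    lines = []

    def fmt(record: str, serial: int, name: str, resname: str, chain: str,
            resseq: int, coords, element: str, charge: int = 0) -> str:
        pdb_name = name if len(name) >= 4 else f" {name:<3s}"
        x, y, z = coords
        chg = "" if charge == 0 else f"{abs(charge)}{'+' if charge > 0 else '-'}"
        return (f"{record:<6s}{serial:>5d} {pdb_name:<4s} {resname:>3s} {chain:1s}"
                f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}{chg:<2s}")

    for res in receptor.residues:
        for a in res.atoms:
            lines.append(fmt("ATOM", a.serial, a.name.replace("'", "'"), res.name,
                             res.chain, res.number, a.coords, a.element, a.formal_charge))
    wserial = max((a.serial for r in receptor.residues for a in r.atoms), default=0)
    for i, w in enumerate(receptor.waters, 1):
        wserial += 1
        lines.append(fmt("HETATM", wserial, "O", "HOH", "W", i, w.coords, "O"))
    for i, ion in enumerate(receptor.ions, 1):
        wserial += 1
        lines.append(fmt("HETATM", wserial, ion.element, ion.element, "I",
                         9000 + i, ion.coords, ion.element, ion.formal_charge))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ligand parsing
# ---------------------------------------------------------------------------

_SOFT_SANITIZE = (Chem.SanitizeFlags.SANITIZE_ALL
                  ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
                  ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)


def _record_from_mol(mol: Chem.Mol, pose_index: int) -> LigandRecord:
    if mol.GetNumConformers() == 0:
        raise ParseError(f"SDF record {pose_index} has no coordinates")
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(serial=a.GetIdx() + 1,
                          name=f"{a.GetSymbol()}{a.GetIdx() + 1}",
                          element=a.GetSymbol().upper(),
                          coords=(p.x, p.y, p.z),
                          formal_charge=a.GetFormalCharge()))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return LigandRecord(title=title, atoms=atoms, bonds=bonds,
                        pose_index=pose_index, mol=mol)


def parse_ligands(sdf_text: str) -> list[LigandRecord]:
    """Parse a (multi-record) V2000/V3000 SDF into :class:`LigandRecord` list.

    Formal charges from ``M  CHG`` blocks are preserved exactly.  Records are
    lightly sanitized (aromaticity/ring perception) without the strict valence
    check, so that deliberately odd species survive parsing; strict
    sanitization happens in :func:`add_hydrogens`.
    """
    if not sdf_text.strip():
        raise ParseError("empty SDF input")
    supplier = Chem.ForwardSDMolSupplier(io.BytesIO(sdf_text.encode("utf-8")),
                                         sanitize=False, removeHs=False)
    records = []
    for i, mol in enumerate(supplier, 1):
        if mol is None:
            raise ParseError(f"SDF record {i} is malformed (atom/bond block inconsistency?)")
        try:
            mol.UpdatePropertyCache(strict=False)
            Chem.SanitizeMol(mol, _SOFT_SANITIZE)
        except Exception as exc:
            raise ParseError(f"SDF record {i}: {exc}") from exc
        records.append(_record_from_mol(mol, i))
    if not records:
        raise ParseError("SDF contains no records")
    return records


def write_ligands_sdf(records: list[LigandRecord]) -> str:
    """Serialize ligand records back to a multi-record SDF string."""
    out = []
    for rec in records:
        mol = Chem.Mol(rec.mol)
        mol.SetProp("_Name", rec.title)
        out.append(Chem.MolToMolBlock(mol, kekulize=False))
        out.append("$$$$\n")
    return "".join(out)


def add_hydrogens(record: LigandRecord, method: str = "rdkit") -> LigandRecord:
    """Add explicit hydrogens to a ligand record.

    ``method="rdkit"`` uses RDKit (strictly sanitizing first, so impossible
    valences raise :class:`SanitizationError`); ``"openbabel"`` uses the
    OpenBabel bindings when available; ``"none"`` returns the input untouched.
    Heavy-atom coordinates are never modified.
    """
    if method == "none":
        return record
    if method == "rdkit":
        mol = Chem.Mol(record.mol)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:
            raise SanitizationError(f"ligand {record.title!r}: {exc}") from exc
        mol = Chem.AddHs(mol, addCoords=True)
        return _record_from_mol(mol, record.pose_index)
    if method == "openbabel":
        try:
            from openbabel import pybel
        except ImportError as exc:  # pragma: no cover - depends on environment
            raise SanitizationError("OpenBabel Python bindings are not available") from exc
        block = Chem.MolToMolBlock(Chem.Mol(record.mol), kekulize=False)
        obmol = pybel.readstring("mol", block)
        obmol.addh()
        out = obmol.write("mol")
        reparsed = parse_ligands(out)[0]
        reparsed.title = record.title
        reparsed.pose_index = record.pose_index
        return reparsed
    raise SanitizationError(f"unknown hydrogen-adding method {method!r}")


# ---------------------------------------------------------------------------
# rigid motions (used by invariance tests and trajectory tooling)
# ---------------------------------------------------------------------------

def _move(coords, R, t):
    return tuple(np.asarray(R, float) @ np.asarray(coords, float) + np.asarray(t, float))


def transform_receptor(receptor: Receptor, R, t) -> Receptor:
    """Apply the rigid motion x -> R x + t to every receptor coordinate."""
    def move_atom(a: Atom) -> Atom:
        return Atom(a.serial, a.name, a.element, _move(a.coords, R, t), a.formal_charge)

    residues = [Residue(r.chain, r.number, r.name, [move_atom(a) for a in r.atoms],
                        dict(r.group_of)) for r in receptor.residues]
    return Receptor(residues=residues,
                    waters=[move_atom(a) for a in receptor.waters],
                    ions=[move_atom(a) for a in receptor.ions],
                    source_path=receptor.source_path)


def transform_ligand(record: LigandRecord, R, t) -> LigandRecord:
    """Apply the rigid motion x -> R x + t to a ligand record (and its mol)."""
    mol = Chem.Mol(record.mol)
    conf = mol.GetConformer()
    for i in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        x, y, z = _move((p.x, p.y, p.z), R, t)
        conf.SetAtomPosition(i, (x, y, z))
    moved = _record_from_mol(mol, record.pose_index)
    moved.title = record.title
    return moved
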