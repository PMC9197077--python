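"""Canonical nucleotide connectivity templates.

PDB files carry no bond orders, so per-residue RDKit molecules are assembled
from these hand-written kekule templates (standard ribo-/deoxyribonucleotide
atom names, PDB v3 primed naming).  Aromaticity, implicit-hydrogen counts and
formal charges then come out of ordinary RDKit sanitization, which makes
SMARTS-based feature perception work identically on receptors and ligands.

Bond orders are kekule structures of the neutral tautomers; one of the two
equivalent anionic phosphate oxygens (OP2, and OP3 when present) carries the
formal -1 charge, OP1 is the P=O oxygen.
"""
from __future__ import annotations

# residue-name aliases -> canonical single letter
RESIDUE_ALIASES = {
    "A": "A", "ADE": "A", "DA": "A",
    "C": "C", "CYT": "C", "DC": "C",
    "G": "G", "GUA": "G", "DG": "G",
    "U": "U", "URA": "U", "URI": "U",
    "T": "T", "THY": "T", "DT": "T",
}

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

#: elements routed to the inorganic-ion list (configurable at parse time)
METAL_SET = {"NA", "K", "MG", "CA", "MN", "FE", "ZN", "CO", "NI", "CU",
             "SR", "BA", "CD", "PB"}

PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'"}
SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}

#: phosphate oxygens always treated as anions regardless of recorded charge
PHOSPHATE_ANIONS = ("OP1", "OP2", "OP3")

# (atom_a, atom_b, bond order); order 1/2; aromatic perception is left to
# sanitization of the kekule form.
_BACKBONE_BONDS = [
    ("P", "OP1", 2), ("P", "OP2", 1), ("P", "OP3", 1), ("P", "O5'", 1),
    ("O5'", "C5'", 1), ("C5'", "C4'", 1), ("C4'", "O4'", 1), ("O4'", "C1'", 1),
    ("C4'", "C3'", 1), ("C3'", "C2'", 1), ("C2'", "C1'", 1),
    ("C3'", "O3'", 1), ("C2'", "O2'", 1),
]

_BASE_BONDS = {
    "A": [
        ("C1'", "N9", 1),
        ("N9", "C8", 1), ("C8", "N7", 2), ("N7", "C5", 1),
        ("C5", "C4", 2), ("C4", "N9", 1),
        ("C4", "N3", 1), ("N3", "C2", 2), ("C2", "N1", 1),
        ("N1", "C6", 2), ("C6", "C5", 1), ("C6", "N6", 1),
    ],
    "G": [
        ("C1'", "N9", 1),
        ("N9", "C8", 1), ("C8", "N7", 2), ("N7", "C5", 1),
        ("C5", "C4", 2), ("C4", "N9", 1),
        ("C4", "N3", 1), ("N3", "C2", 2), ("C2", "N1", 1),
        ("N1", "C6", 1), ("C6", "C5", 1), ("C6", "O6", 2), ("C2", "N2", 1),
    ],
    "C": [
        ("C1'", "N1", 1),
        ("N1", "C2", 1), ("C2", "O2", 2), ("C2", "N3", 1),
        ("N3", "C4", 2), ("C4", "N4", 1), ("C4", "C5", 1),
        ("C5", "C6", 2), ("C6", "N1", 1),
    ],
    "U": [
        ("C1'", "N1", 1),
        ("N1", "C2", 1), ("C2", "O2", 2), ("C2", "N3", 1),
        ("N3", "C4", 1), ("C4", "O4", 2), ("C4", "C5", 1),
        ("C5", "C6", 2), ("C6", "N1", 1),
    ],
}
_BASE_BONDS["T"] = _BASE_BONDS["U"] + [("C5", "C7", 1)]

#: formal charges applied when the named atom is present
TEMPLATE_CHARGES = {"OP2": -1, "OP3": -1}

#: base atoms of the purine/pyrimidine rings plus exocyclic substituents
BASE_ATOMS = {
    "A": {"N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"},
    "G": {"N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "O6", "N2"},
    "C": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"},
    "U": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"},
    "T": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6", "C7"},
}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U", "T"}


def residue_bonds(letter: str):
    """Backbone + base bond table for a canonical nucleotide letter."""
    return _BACKBONE_BONDS + _BASE_BONDS[letter]


def canonical_letter(residue_name: str) -> str | None:
    """Canonical A/C/G/U/T letter for a residue name, or None if unknown."""
    return RESIDUE_ALIASES.get(residue_name.strip().upper())


def best_template(residue_name: str, atom_names) -> str | None:
    """Template letter for a residue: by name, else by base-atom overlap.

    Modified nucleotides whose names are not in the alias table are matched
    to the canonical base sharing the largest base-atom-name overlap; returns
    None when there is no overlap at all (not a nucleotide).
    """
    letter = canonical_letter(residue_name)
    if letter is not None:
        return letter
    names = {n for n in atom_names}
    best, best_overlap = None, 0
    for cand, atoms in BASE_ATOMS.items():
        overlap = len(names & atoms)
        if overlap > best_overlap:
            best, best_overlap = cand, overlap
    if best_overlap == 0 and not (names & (PHOSPHATE_ATOMS | SUGAR_ATOMS)):
        return None
    return best or "U"
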