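"""User-defined interaction types loaded from YAML.

A plugin names one interaction channel and defines it by a receptor-side
SMARTS, a ligand-side SMARTS and a geometric criterion: a distance window,
optionally sharpened by an angle or a dihedral over *anchor atoms*.  Anchors
are written ``R<i>`` / ``L<i>`` and are 1-based positions inside the
receptor/ligand SMARTS match tuple (so ``R2`` is the second atom matched by
the receptor pattern).  Example file::

    plugins:
      - name: n_pi_star
        receptor_smarts: "[OX1]=[CX3]"
        ligand_smarts: "[O,N;X1,X2,X3]"
        distance: {min: 0.0, max: 3.6, receptor_atom: 1, ligand_atom: 1}
        angle: {min: 95.0, max: 125.0, atoms: [L1, R1, R2]}

Plugin channels are appended to a FULL fingerprint after the twelve fixed
channels, in file order; they never alter the fixed channels' bits.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .chem_perception import as_mol, compile_smarts, match_smarts
from .config import GeometryConfig
from .detectors import InteractionRecord
from .errors import PatternError, PluginSchemaError
from .geometry import EPS, angle_deg, dihedral_deg, distance
from .model_io import LigandRecord, Residue


@dataclass(frozen=True)
class Anchor:
    side: str      # "R" or "L"
    position: int  # 1-based index into the SMARTS match tuple


def _parse_anchor(text) -> Anchor:
    if not isinstance(text, str) or len(text) < 2 or text[0] not in "RL" \
            or not text[1:].isdigit():
        raise PluginSchemaError(f"bad anchor {text!r}: expected R<i> or L<i>")
    return Anchor(side=text[0], position=int(text[1:]))


@dataclass(frozen=True)
class PluginDefinition:
    name: str
    receptor_smarts: str
    ligand_smarts: str
    dmin: float
    dmax: float
    distance_anchors: tuple[Anchor, Anchor]              # (receptor, ligand)
    angle: tuple[float, float, tuple[Anchor, ...]] | None = None
    dihedral: tuple[float, float, tuple[Anchor, ...]] | None = None


def _validate_anchors(defn: PluginDefinition) -> None:
    try:
        n_r = compile_smarts(defn.receptor_smarts).GetNumAtoms()
        n_l = compile_smarts(defn.ligand_smarts).GetNumAtoms()
    except PatternError as exc:
        raise PluginSchemaError(f"plugin {defn.name!r}: {exc}") from exc
    anchors = list(defn.distance_anchors)
    for crit in (defn.angle, defn.dihedral):
        if crit:
            anchors.extend(crit[2])
    for a in anchors:
        limit = n_r if a.side == "R" else n_l
        if not 1 <= a.position <= limit:
            raise PluginSchemaError(
                f"plugin {defn.name!r}: anchor {a.side}{a.position} exceeds the "
                f"{'receptor' if a.side == 'R' else 'ligand'} SMARTS match size {limit}")


def _parse_plugin(entry, index: int) -> PluginDefinition:
    if not isinstance(entry, dict):
        raise PluginSchemaError(f"plugin #{index}: expected a mapping")
    try:
        name = entry["name"]
        receptor_smarts = entry["receptor_smarts"]
        ligand_smarts = entry["ligand_smarts"]
        dist = entry["distance"]
    except KeyError as exc:
        raise PluginSchemaError(f"plugin #{index}: missing key {exc}") from exc
    if not isinstance(dist, dict) or "max" not in dist:
        raise PluginSchemaError(f"plugin {name!r}: distance criterion needs a 'max'")
    if "angle" in entry and "dihedral" in entry:
        raise PluginSchemaError(f"plugin {name!r}: angle and dihedral are exclusive")

    def window(block, n_anchors, what):
        if not isinstance(block, dict) or "atoms" not in block:
            raise PluginSchemaError(f"plugin {name!r}: {what} criterion needs 'atoms'")
        anchors = tuple(_parse_anchor(a) for a in block["atoms"])
        if len(anchors) != n_anchors:
            raise PluginSchemaError(
                f"plugin {name!r}: {what} needs exactly {n_anchors} anchor atoms")
        return (float(block.get("min", 0.0)), float(block.get("max", 180.0)), anchors)

    defn = PluginDefinition(
        name=str(name),
        receptor_smarts=str(receptor_smarts),
        ligand_smarts=str(ligand_smarts),
        dmin=float(dist.get("min", 0.0)),
        dmax=float(dist["max"]),
        distance_anchors=(Anchor("R", int(dist.get("receptor_atom", 1))),
                          Anchor("L", int(dist.get("ligand_atom", 1)))),
        angle=window(entry["angle"], 3, "angle") if "angle" in entry else None,
        dihedral=window(entry["dihedral"], 4, "dihedral") if "dihedral" in entry else None,
    )
    _validate_anchors(defn)
    return defn


def load_plugin_file(yaml_text: str) -> list[PluginDefinition]:
    """Parse a plugin YAML document into definitions, in file order."""
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise PluginSchemaError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("plugins"), list):
        raise PluginSchemaError("plugin file must contain a top-level 'plugins' list")
    defns = [_parse_plugin(entry, i) for i, entry in enumerate(doc["plugins"], 1)]
    names = [d.name for d in defns]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise PluginSchemaError(f"duplicate plugin names: {sorted(dupes)}")
    return defns


def sample_plugin_text() -> str:
    """The shipped sample plugin set (reconstructions; see the file header)."""
    return resources.files("nasift").joinpath("data/sample_plugins.yaml").read_text()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _anchor_coords(anchor: Anchor, r_match, l_match, r_conf, l_conf):
    if anchor.side == "R":
        idx = r_match[anchor.position - 1]
        p = r_conf.GetAtomPosition(idx)
    else:
        idx = l_match[anchor.position - 1]
        p = l_conf.GetAtomPosition(idx)
    return (p.x, p.y, p.z)


def evaluate_plugin(defn: PluginDefinition, residue: Residue, ligand: LigandRecord,
                    cfg: GeometryConfig) -> list[InteractionRecord]:
    """Evaluate one plugin on a (residue, ligand) pair.

    One record is emitted per (receptor match, ligand match) pair whose
    distance — and angle or dihedral, when defined — satisfies the criterion.
    ``cfg`` is accepted for interface symmetry with the built-in detectors;
    plugin thresholds live in the definition itself.
    """
    r_mol = as_mol(residue)
    l_mol = as_mol(ligand)
    r_matches = match_smarts(r_mol, defn.receptor_smarts)
    l_matches = match_smarts(l_mol, defn.ligand_smarts)
    if not r_matches or not l_matches:
        return []
    r_conf = r_mol.GetConformer()
    l_conf = l_mol.GetConformer()
    r_labels = [a.name for a in residue.atoms]
    l_labels = [f"{a.element.capitalize()}{i + 1}" for i, a in enumerate(ligand.atoms)]

    records = []
    for rm in r_matches:
        for lm in l_matches:
            ra, la = defn.distance_anchors
            p_r = _anchor_coords(ra, rm, lm, r_conf, l_conf)
            p_l = _anchor_coords(la, rm, lm, r_conf, l_conf)
            d = distance(p_r, p_l)
            if not (defn.dmin - EPS <= d <= defn.dmax + EPS):
                continue
            ang = None
            if defn.angle:
                amin, amax, anchors = defn.angle
                pts = [_anchor_coords(a, rm, lm, r_conf, l_conf) for a in anchors]
                ang = angle_deg(*pts)
                if not (amin - EPS <= ang <= amax + EPS):
                    continue
            if defn.dihedral:
                amin, amax, anchors = defn.dihedral
                pts = [_anchor_coords(a, rm, lm, r_conf, l_conf) for a in anchors]
                ang = dihedral_deg(*pts)
                if not (amin - EPS <= ang <= amax + EPS):
                    continue
            records.append(InteractionRecord(
                itype=defn.name, residue=residue.key,
                receptor_side=r_labels[rm[ra.position - 1]],
                ligand_side=l_labels[lm[la.position - 1]],
                distance=d, angle=ang,
                receptor_xyz=p_r, ligand_xyz=p_l))
    # collapse duplicates (several SMARTS matches can share anchor atoms)
    seen, out = set(), []
    for r in records:
        if r.key not in seen:
            seen.add(r.key)
            out.append(r)
    return out
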