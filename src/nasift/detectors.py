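"""Geometric detection of the nine built-in non-covalent interaction classes.

Each detector takes the perceived :class:`~nasift.chem_perception.FeatureSet`
of one receptor residue and one ligand record plus a
:class:`~nasift.config.GeometryConfig` and emits
:class:`InteractionRecord` objects.  Both interaction directions are always
evaluated where chemically meaningful (the receptor acts as hydrogen-bond
donor *and* acceptor, phosphates act as anion partners toward ligand cations
*and* as "anion donors" toward ligand aromatic rings, ...).

Records are deduplicated on (type, receptor side, ligand side, mediator).
Every ``<=`` distance/angle comparison adds a 1e-9 guard
(:data:`nasift.geometry.EPS`) so that geometries constructed exactly at a
cutoff are detected; a donor-acceptor pair at 3.90 A is a hydrogen bond,
at 3.91 A it is not.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_perception import (
    DEFAULT_RULES,
    FeatureAtom,
    FeatureSet,
    PerceptionRules,
    ion_features,
    perceive_features,
    water_features,
)
from .config import GeometryConfig
from .errors import MissingHydrogenError
from .geometry import EPS, angle_deg, distance, folded_angle, plane_offset, vector_angle_deg
from .model_io import Group, LigandRecord, Receptor, Residue

#: the fixed FULL-variant channel registry, in fingerprint order
FIXED_CHANNELS = (
    "HB", "HAL", "CationAnion", "PiCation", "PiAnion", "PiStacking",
    "Mg_mediated", "K_mediated", "Na_mediated", "OtherMetal_mediated",
    "Water_mediated", "Lipophilic",
)

_ION_CHANNEL = {"MG": "Mg_mediated", "K": "K_mediated", "NA": "Na_mediated"}

_UNKNOWN_RESIDUE = ("?", 0, "?")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected contact between a receptor residue and a ligand record."""
    itype: str
    residue: tuple[str, int, str]
    receptor_side: str
    ligand_side: str
    distance: float
    angle: float | None = None
    subtype: str = ""
    mediator: str = ""
    receptor_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ligand_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mediator_xyz: tuple[float, float, float] | None = None
    ligand_title: str = ""
    pose: int = 0

    @property
    def key(self):
        return (self.itype, self.residue, self.receptor_side, self.ligand_side, self.mediator)


def _dedup(records):
    out = {}
    for r in records:
        out.setdefault(r.key, r)
    return list(out.values())


def _le(value: float, cutoff: float) -> bool:
    return value <= cutoff + EPS


def _within_window(angle: float, center: float, window: float) -> bool:
    return abs(angle - center) <= window + EPS


# ---------------------------------------------------------------------------
# pairwise detectors
# ---------------------------------------------------------------------------


def detect_hydrogen_bonds(residue_features: FeatureSet, ligand_features: FeatureSet,
                          cfg: GeometryConfig, mode: str = "distance_only",
                          residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """Hydrogen bonds, by D...A distance alone or the stricter D-H...A variant.

    ``distance_only`` fires for every donor-heavy-atom/acceptor pair within
    ``hb_dist_max``; ``dha`` additionally requires a donor hydrogen with
    D-H...A angle of at least ``hb_dha_angle_min`` and therefore explicit
    hydrogens on any donor that comes within range.
    """
    if mode not in ("distance_only", "dha"):
        raise ValueError(f"unknown hydrogen-bond mode {mode!r}")
    records = []
    directions = (
        (residue_features.hb_donors, ligand_features.hb_acceptors, True),
        (ligand_features.hb_donors, residue_features.hb_acceptors, False),
    )
    for donors, acceptors, receptor_is_donor in directions:
        for donor in donors:
            for acc in acceptors:
                d = distance(donor.heavy.xyz, acc.xyz)
                if not _le(d, cfg.hb_dist_max):
                    continue
                ang = None
                if mode == "dha":
                    if not donor.hydrogens:
                        raise MissingHydrogenError(
                            f"donor {donor.heavy.label} has no explicit hydrogen "
                            "but D-H...A mode was requested")
                    ang = max(angle_deg(donor.heavy.xyz, h.xyz, acc.xyz)
                              for h in donor.hydrogens)
                    if ang < cfg.hb_dha_angle_min - EPS:
                        continue
                rec_side, lig_side = ((donor.heavy, acc) if receptor_is_donor
                                      else (acc, donor.heavy))
                records.append(InteractionRecord(
                    itype="HB", residue=residue_key,
                    receptor_side=rec_side.label, ligand_side=lig_side.label,
                    distance=d, angle=ang,
                    subtype="receptor-donor" if receptor_is_donor else "ligand-donor",
                    receptor_xyz=rec_side.coords, ligand_xyz=lig_side.coords))
    return _dedup(records)


def detect_halogen_bonds(residue_features: FeatureSet, ligand_features: FeatureSet,
                         cfg: GeometryConfig,
                         residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """C-X...A halogen bonds (X = Cl/Br/I from the ligand, A on the receptor).

    Requires X...A within ``hal_dist_max``, a donor angle C-X...A inside the
    ``hal_don_angle`` window and an acceptor angle X...A-Y inside the
    ``hal_acc_angle`` window, where Y is the acceptor's single heavy neighbor.
    """
    records = []
    for carbon, halogen in ligand_features.halogen_donors:
        for acc in residue_features.hb_acceptors:
            if len(acc.neighbors) != 1:
                continue
            d = distance(halogen.xyz, acc.xyz)
            if not _le(d, cfg.hal_dist_max):
                continue
            don_angle = angle_deg(carbon.xyz, halogen.xyz, acc.xyz)
            if not _within_window(don_angle, cfg.hal_don_angle, cfg.hal_don_angle_window):
                continue
            acc_angle = angle_deg(halogen.xyz, acc.xyz, np.asarray(acc.neighbors[0]))
            if not _within_window(acc_angle, cfg.hal_acc_angle, cfg.hal_acc_angle_window):
                continue
            records.append(InteractionRecord(
                itype="HAL", residue=residue_key,
                receptor_side=acc.label, ligand_side=halogen.label,
                distance=d, angle=don_angle,
                receptor_xyz=acc.coords, ligand_xyz=halogen.coords))
    return _dedup(records)


def detect_cation_anion(residue_features: FeatureSet, ligand_features: FeatureSet,
                        cfg: GeometryConfig,
                        residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """Salt bridges: charged-atom pairs with ca_dist_min < d <= ca_dist_max."""
    records = []
    directions = (
        (residue_features.anions, ligand_features.cations, True),
        (residue_features.cations, ligand_features.anions, False),
    )
    for rside, lside, _ in directions:
        for r_atom in rside:
            for l_atom in lside:
                d = distance(r_atom.xyz, l_atom.xyz)
                if d > cfg.ca_dist_min and _le(d, cfg.ca_dist_max):
                    records.append(InteractionRecord(
                        itype="CationAnion", residue=residue_key,
                        receptor_side=r_atom.label, ligand_side=l_atom.label,
                        distance=d,
                        receptor_xyz=r_atom.coords, ligand_xyz=l_atom.coords))
    return _dedup(records)


def detect_pi_ion(residue_features: FeatureSet, ligand_features: FeatureSet,
                  cfg: GeometryConfig, ion_kind: str,
                  residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """Pi-cation / Pi-anion: a charged atom over an aromatic ring face.

    Fires when the centroid-ion distance is within ``pi_ion_dist_max`` and
    the angle between the ring normal and the centroid->ion vector (folded
    onto [0, 90]) is within ``pi_ion_angle_max``.  Both directions count:
    nucleobase ring vs ligand ion, and ligand ring vs receptor charge (the
    phosphate acting as "anion donor").
    """
    if ion_kind not in ("cation", "anion"):
        raise ValueError(f"ion_kind must be cation or anion, got {ion_kind!r}")
    itype = "PiCation" if ion_kind == "cation" else "PiAnion"
    pick = (lambda fs: fs.cations) if ion_kind == "cation" else (lambda fs: fs.anions)
    records = []
    combos = (
        (residue_features.rings, pick(ligand_features), True),
        (ligand_features.rings, pick(residue_features), False),
    )
    for rings, ions, ring_on_receptor in combos:
        for ring in rings:
            for ion in ions:
                d = distance(ring.centroid_xyz, ion.xyz)
                if not _le(d, cfg.pi_ion_dist_max):
                    continue
                theta = folded_angle(vector_angle_deg(ring.normal_xyz,
                                                      ion.xyz - ring.centroid_xyz))
                if theta > cfg.pi_ion_angle_max + EPS:
                    continue
                rec_side, lig_side = ((ring.label, ion.label) if ring_on_receptor
                                      else (ion.label, ring.label))
                rec_xyz, lig_xyz = ((ring.centroid, ion.coords) if ring_on_receptor
                                    else (ion.coords, ring.centroid))
                records.append(InteractionRecord(
                    itype=itype, residue=residue_key,
                    receptor_side=rec_side, ligand_side=lig_side,
                    distance=d, angle=theta,
                    subtype="Pi-cation" if ion_kind == "cation" else "Pi-anion",
                    receptor_xyz=rec_xyz, ligand_xyz=lig_xyz))
    return _dedup(records)


def detect_pi_stacking(residue_features: FeatureSet, ligand_features: FeatureSet,
                       cfg: GeometryConfig,
                       residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """Aromatic ring-ring stacking, subtyped sandwich / parallel-displaced / T-shaped.

    With centroid distance d, interplanar angle theta (folded to [0, 90]) and
    in-plane centroid offset o (the smaller of the two projections), a pair
    stacks if d <= pi_stack_dist_max and either theta is inside the parallel
    window with o <= pi_stack_offset_max, or theta falls in the T-shape
    window.  Purine bases contribute their 5- and 6-membered rings
    independently.
    """
    records = []
    for r_ring in residue_features.rings:
        for l_ring in ligand_features.rings:
            d = distance(r_ring.centroid_xyz, l_ring.centroid_xyz)
            if not _le(d, cfg.pi_stack_dist_max):
                continue
            theta = folded_angle(vector_angle_deg(r_ring.normal_xyz, l_ring.normal_xyz))
            offset = min(plane_offset(r_ring.centroid_xyz, r_ring.normal_xyz,
                                      l_ring.centroid_xyz),
                         plane_offset(l_ring.centroid_xyz, l_ring.normal_xyz,
                                      r_ring.centroid_xyz))
            subtype = None
            if theta <= cfg.pi_stack_parallel_angle_max + EPS and \
                    _le(offset, cfg.pi_stack_offset_max):
                subtype = ("sandwich" if offset <= cfg.pi_stack_sandwich_offset + EPS
                           else "parallel-displaced")
            elif cfg.pi_stack_tshape_angle_min - EPS <= theta <= \
                    cfg.pi_stack_tshape_angle_max + EPS:
                subtype = "T-shaped"
            if subtype is None:
                continue
            records.append(InteractionRecord(
                itype="PiStacking", residue=residue_key,
                receptor_side=r_ring.label, ligand_side=l_ring.label,
                distance=d, angle=theta, subtype=subtype,
                receptor_xyz=r_ring.centroid, ligand_xyz=l_ring.centroid))
    return _dedup(records)


def _coordination_partners(fs: FeatureSet) -> list[FeatureAtom]:
    """N/O atoms able to coordinate a metal: acceptors plus anions."""
    seen, out = set(), []
    for atom in list(fs.hb_acceptors) + list(fs.anions):
        if atom.element in ("N", "O") and atom.label not in seen:
            seen.add(atom.label)
            out.append(atom)
    return out


def detect_ion_mediated(residue_features: FeatureSet, ligand_features: FeatureSet,
                        receptor_ions: list[FeatureAtom], cfg: GeometryConfig,
                        residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """Metal-cation bridges: residue partner - M - ligand partner.

    Fires when both coordination legs are within the per-element cutoff;
    the channel is Mg/K/Na or OtherMetal by the bridging element.  The
    record's distance is the longer (binding-limiting) coordination leg.
    """
    r_partners = _coordination_partners(residue_features)
    l_partners = _coordination_partners(ligand_features)
    records = []
    for ion in receptor_ions:
        cutoff = cfg.ion_cutoff(ion.element)
        channel = _ION_CHANNEL.get(ion.element.upper(), "OtherMetal_mediated")
        for rp in r_partners:
            d1 = distance(rp.xyz, ion.xyz)
            if not _le(d1, cutoff):
                continue
            for lp in l_partners:
                d2 = distance(lp.xyz, ion.xyz)
                if not _le(d2, cutoff):
                    continue
                records.append(InteractionRecord(
                    itype=channel, residue=residue_key,
                    receptor_side=rp.label, ligand_side=lp.label,
                    distance=max(d1, d2), mediator=ion.label,
                    receptor_xyz=rp.coords, ligand_xyz=lp.coords,
                    mediator_xyz=ion.coords))
    return _dedup(records)


def _polar_partners(fs: FeatureSet) -> list[FeatureAtom]:
    seen, out = set(), []
    for atom in [d.heavy for d in fs.hb_donors] + list(fs.hb_acceptors):
        if atom.label not in seen:
            seen.add(atom.label)
            out.append(atom)
    return out


def detect_water_mediated(residue_features: FeatureSet, ligand_features: FeatureSet,
                          receptor_waters: list[FeatureAtom], cfg: GeometryConfig,
                          residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """Water bridges: both polar partners within water_mediated_dist_max of one W."""
    r_partners = _polar_partners(residue_features)
    l_partners = _polar_partners(ligand_features)
    records = []
    for water in receptor_waters:
        for rp in r_partners:
            d1 = distance(rp.xyz, water.xyz)
            if not _le(d1, cfg.water_mediated_dist_max):
                continue
            for lp in l_partners:
                d2 = distance(lp.xyz, water.xyz)
                if not _le(d2, cfg.water_mediated_dist_max):
                    continue
                records.append(InteractionRecord(
                    itype="Water_mediated", residue=residue_key,
                    receptor_side=rp.label, ligand_side=lp.label,
                    distance=max(d1, d2), mediator=water.label,
                    receptor_xyz=rp.coords, ligand_xyz=lp.coords,
                    mediator_xyz=water.coords))
    return _dedup(records)


def detect_lipophilic(residue_features: FeatureSet, ligand_features: FeatureSet,
                      cfg: GeometryConfig,
                      residue_key=_UNKNOWN_RESIDUE) -> list[InteractionRecord]:
    """Apolar contacts: lipophilic atom pairs within lipophilic_dist_max."""
    records = []
    for r_atom in residue_features.lipophilic:
        for l_atom in ligand_features.lipophilic:
            d = distance(r_atom.xyz, l_atom.xyz)
            if _le(d, cfg.lipophilic_dist_max):
                records.append(InteractionRecord(
                    itype="Lipophilic", residue=residue_key,
                    receptor_side=r_atom.label, ligand_side=l_atom.label,
                    distance=d,
                    receptor_xyz=r_atom.coords, ligand_xyz=l_atom.coords))
    return _dedup(records)


def detect_contact(residue: Residue, ligand: LigandRecord, cfg: GeometryConfig,
                   granularity: str = "residue"):
    """Any-heavy-atom contact bit(s): one bit per residue (SIMPLE) or three
    bits in phosphate/sugar/base order (PBS), using simple_contact_dist_max."""
    lig_xyz = np.array([a.coords for a in ligand.atoms if not a.is_hydrogen], float)
    res_heavy = [a for a in residue.atoms if not a.is_hydrogen]
    if granularity == "residue":
        if lig_xyz.size == 0 or not res_heavy:
            return 0
        res_xyz = np.array([a.coords for a in res_heavy], float)
        dmin = np.sqrt(((res_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(-1)).min()
        return int(_le(float(dmin), cfg.simple_contact_dist_max))
    if granularity == "group":
        bits = []
        for group in (Group.PHOSPHATE, Group.SUGAR, Group.BASE):
            atoms = [a for a in res_heavy if residue.group_of.get(a.name) is group]
            if not atoms or lig_xyz.size == 0:
                bits.append(0)
                continue
            gxyz = np.array([a.coords for a in atoms], float)
            dmin = np.sqrt(((gxyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(-1)).min()
            bits.append(int(_le(float(dmin), cfg.simple_contact_dist_max)))
        return tuple(bits)
    raise ValueError(f"unknown granularity {granularity!r}")


# ---------------------------------------------------------------------------
# orchestration over a whole receptor
# ---------------------------------------------------------------------------

#: generous residue-ligand pre-filter; the farthest-reaching interaction is a
#: double 3.5 A water bridge (partners up to 7 A apart)
_PREFILTER_DIST = 14.0


def receptor_features(receptor: Receptor,
                      rules: PerceptionRules = DEFAULT_RULES) -> list[tuple[Residue, FeatureSet]]:
    """Perceive (and cache) features for every residue of a receptor."""
    cache = getattr(receptor, "_feature_cache", None)
    if cache is not None and cache[0] == rules:
        return cache[1]
    from .chem_perception import residue_to_mol  # local import to avoid cycle noise

    p_coords = []
    for res in receptor.residues:
        try:
            p_coords.append(res.atom("P").xyz)
        except KeyError:
            pass
    out = []
    for res in receptor.residues:
        bridged = False
        try:
            o3 = res.atom("O3'").xyz
            bridged = any(np.linalg.norm(p - o3) < 1.8 for p in p_coords)
        except KeyError:
            pass
        # bind the template-built mol to the residue so perception (and any
        # later SMARTS matching, e.g. by plugins) reuses it
        res._mol = residue_to_mol(res, o3_bridged=bridged)
        fs = perceive_features(res, role="receptor_residue", rules=rules)
        out.append((res, fs))
    receptor._feature_cache = (rules, out)
    return out


def detect_all(receptor: Receptor, ligand: LigandRecord, cfg: GeometryConfig,
               hb_mode: str = "distance_only",
               rules: PerceptionRules = DEFAULT_RULES) -> list[InteractionRecord]:
    """Run every FULL-variant detector for one receptor/ligand pair."""
    lfeat = perceive_features(ligand, role="ligand", rules=rules)
    waters = water_features(receptor.waters)
    ions = ion_features(receptor.ions)
    lig_xyz = np.array([a.coords for a in ligand.atoms if not a.is_hydrogen], float)

    records: list[InteractionRecord] = []
    for res, rfeat in receptor_features(receptor, rules):
        res_xyz = np.array([a.coords for a in res.atoms if not a.is_hydrogen], float)
        if lig_xyz.size and res_xyz.size:
            dmin = np.sqrt(((res_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(-1)).min()
            if dmin > _PREFILTER_DIST:
                continue
        key = res.key
        records += detect_hydrogen_bonds(rfeat, lfeat, cfg, hb_mode, residue_key=key)
        records += detect_halogen_bonds(rfeat, lfeat, cfg, residue_key=key)
        records += detect_cation_anion(rfeat, lfeat, cfg, residue_key=key)
        records += detect_pi_ion(rfeat, lfeat, cfg, "cation", residue_key=key)
        records += detect_pi_ion(rfeat, lfeat, cfg, "anion", residue_key=key)
        records += detect_pi_stacking(rfeat, lfeat, cfg, residue_key=key)
        records += detect_ion_mediated(rfeat, lfeat, ions, cfg, residue_key=key)
        records += detect_water_mediated(rfeat, lfeat, waters, cfg, residue_key=key)
        records += detect_lipophilic(rfeat, lfeat, cfg, residue_key=key)
    from dataclasses import replace
    return [replace(r, ligand_title=ligand.title, pose=ligand.pose_index) for r in records]
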