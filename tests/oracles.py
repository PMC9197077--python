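"""Brute-force interaction oracles.

Plain double-loop re-evaluation of every geometric predicate, written
independently of the package's detector implementations (no nasift.geometry,
no vectorization): used to verify detector output record-for-record on
randomized feature scenes.  Comparisons share the documented 1e-9 cutoff
guard so that exact-boundary constructions agree.
"""
from __future__ import annotations

import math

EPS = 1e-9

ALL_CHANNELS = ("HB", "HAL", "CationAnion", "PiCation", "PiAnion", "PiStacking",
                "Mg_mediated", "K_mediated", "Na_mediated", "OtherMetal_mediated",
                "Water_mediated", "Lipophilic")

_ION_CHANNEL = {"MG": "Mg_mediated", "K": "K_mediated", "NA": "Na_mediated"}


def _d(p, q):
    return math.dist(p, q)


def _sub(p, q):
    return [a - b for a, b in zip(p, q)]


def _norm(v):
    return math.sqrt(sum(x * x for x in v))


def _angle(a, b, c):
    """Angle at vertex b, degrees."""
    v1 = _sub(a, b)
    v2 = _sub(c, b)
    cosv = sum(x * y for x, y in zip(v1, v2)) / (_norm(v1) * _norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _vec_angle(u, v):
    cosv = sum(x * y for x, y in zip(u, v)) / (_norm(u) * _norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _fold(theta):
    theta = theta % 180.0
    return min(theta, 180.0 - theta)


def _offset(centroid_a, normal_a, centroid_b):
    dvec = _sub(centroid_b, centroid_a)
    along = sum(x * y for x, y in zip(dvec, normal_a))
    perp = [x - along * n for x, n in zip(dvec, normal_a)]
    return _norm(perp)


def oracle_keys(channel, rfeat, lfeat, waters, ions, cfg, hb_mode="distance_only"):
    """Set of (receptor_side, ligand_side, mediator) keys the predicate allows."""
    keys = set()
    if channel == "HB":
        for donors, acceptors, r_is_d in ((rfeat.hb_donors, lfeat.hb_acceptors, True),
                                          (lfeat.hb_donors, rfeat.hb_acceptors, False)):
            for dn in donors:
                for ac in acceptors:
                    if _d(dn.heavy.coords, ac.coords) > cfg.hb_dist_max + EPS:
                        continue
                    if hb_mode == "dha":
                        ok = any(_angle(dn.heavy.coords, h.coords, ac.coords)
                                 >= cfg.hb_dha_angle_min - EPS for h in dn.hydrogens)
                        if not ok:
                            continue
                    pair = ((dn.heavy.label, ac.label) if r_is_d
                            else (ac.label, dn.heavy.label))
                    keys.add((pair[0], pair[1], ""))
    elif channel == "HAL":
        for carbon, hal in lfeat.halogen_donors:
            for ac in rfeat.hb_acceptors:
                if len(ac.neighbors) != 1:
                    continue
                if _d(hal.coords, ac.coords) > cfg.hal_dist_max + EPS:
                    continue
                if abs(_angle(carbon.coords, hal.coords, ac.coords)
                       - cfg.hal_don_angle) > cfg.hal_don_angle_window + EPS:
                    continue
                if abs(_angle(hal.coords, ac.coords, ac.neighbors[0])
                       - cfg.hal_acc_angle) > cfg.hal_acc_angle_window + EPS:
                    continue
                keys.add((ac.label, hal.label, ""))
    elif channel == "CationAnion":
        for rs, ls in ((rfeat.anions, lfeat.cations), (rfeat.cations, lfeat.anions)):
            for r in rs:
                for l in ls:
                    d = _d(r.coords, l.coords)
                    if cfg.ca_dist_min < d <= cfg.ca_dist_max + EPS:
                        keys.add((r.label, l.label, ""))
    elif channel in ("PiCation", "PiAnion"):
        pick = (lambda fs: fs.cations) if channel == "PiCation" else (lambda fs: fs.anions)
        for rings, charges, ring_on_r in ((rfeat.rings, pick(lfeat), True),
                                          (lfeat.rings, pick(rfeat), False)):
            for ring in rings:
                for ion in charges:
                    if _d(ring.centroid, ion.coords) > cfg.pi_ion_dist_max + EPS:
                        continue
                    theta = _fold(_vec_angle(ring.normal, _sub(ion.coords, ring.centroid)))
                    if theta > cfg.pi_ion_angle_max + EPS:
                        continue
                    keys.add((ring.label, ion.label, "") if ring_on_r
                             else (ion.label, ring.label, ""))
    elif channel == "PiStacking":
        for r in rfeat.rings:
            for l in lfeat.rings:
                if _d(r.centroid, l.centroid) > cfg.pi_stack_dist_max + EPS:
                    continue
                theta = _fold(_vec_angle(r.normal, l.normal))
                off = min(_offset(r.centroid, r.normal, l.centroid),
                          _offset(l.centroid, l.normal, r.centroid))
                parallel = (theta <= cfg.pi_stack_parallel_angle_max + EPS
                            and off <= cfg.pi_stack_offset_max + EPS)
                tshape = (cfg.pi_stack_tshape_angle_min - EPS <= theta
                          <= cfg.pi_stack_tshape_angle_max + EPS)
                if parallel or tshape:
                    keys.add((r.label, l.label, ""))
    elif channel in ("Mg_mediated", "K_mediated", "Na_mediated", "OtherMetal_mediated"):
        def partners(fs):
            out, seen = [], set()
            for atom in list(fs.hb_acceptors) + list(fs.anions):
                if atom.element in ("N", "O") and atom.label not in seen:
                    seen.add(atom.label)
                    out.append(atom)
            return out

        for ion in ions:
            if _ION_CHANNEL.get(ion.element.upper(), "OtherMetal_mediated") != channel:
                continue
            cutoff = cfg.ion_mediated_dist_max.get(
                ion.element.upper(), cfg.ion_mediated_dist_max["other"])
            for rp in partners(rfeat):
                if _d(rp.coords, ion.coords) > cutoff + EPS:
                    continue
                for lp in partners(lfeat):
                    if _d(lp.coords, ion.coords) > cutoff + EPS:
                        continue
                    keys.add((rp.label, lp.label, ion.label))
    elif channel == "Water_mediated":
        def polar(fs):
            out, seen = [], set()
            for atom in [d.heavy for d in fs.hb_donors] + list(fs.hb_acceptors):
                if atom.label not in seen:
                    seen.add(atom.label)
                    out.append(atom)
            return out

        for w in waters:
            for rp in polar(rfeat):
                if _d(rp.coords, w.coords) > cfg.water_mediated_dist_max + EPS:
                    continue
                for lp in polar(lfeat):
                    if _d(lp.coords, w.coords) > cfg.water_mediated_dist_max + EPS:
                        continue
                    keys.add((rp.label, lp.label, w.label))
    elif channel == "Lipophilic":
        for r in rfeat.lipophilic:
            for l in lfeat.lipophilic:
                if _d(r.coords, l.coords) <= cfg.lipophilic_dist_max + EPS:
                    keys.add((r.label, l.label, ""))
    else:
        raise ValueError(channel)
    return keys


def detector_for(channel):
    """The package detector whose output the oracle checks, as a callable
    scene -> record list."""
    from nasift import detectors as det

    def run(scene, cfg, hb_mode="distance_only"):
        r, l = scene.residue_features, scene.ligand_features
        if channel == "HB":
            return det.detect_hydrogen_bonds(r, l, cfg, hb_mode)
        if channel == "HAL":
            return det.detect_halogen_bonds(r, l, cfg)
        if channel == "CationAnion":
            return det.detect_cation_anion(r, l, cfg)
        if channel == "PiCation":
            return det.detect_pi_ion(r, l, cfg, "cation")
        if channel == "PiAnion":
            return det.detect_pi_ion(r, l, cfg, "anion")
        if channel == "PiStacking":
            return det.detect_pi_stacking(r, l, cfg)
        if channel in ("Mg_mediated", "K_mediated", "Na_mediated", "OtherMetal_mediated"):
            return [x for x in det.detect_ion_mediated(r, l, scene.ions, cfg)
                    if x.itype == channel]
        if channel == "Water_mediated":
            return det.detect_water_mediated(r, l, scene.waters, cfg)
        if channel == "Lipophilic":
            return det.detect_lipophilic(r, l, cfg)
        raise ValueError(channel)

    return run
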