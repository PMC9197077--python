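"""Geometric interaction detectors: unit geometry, oracles and invariances."""
import dataclasses

import numpy as np
import pytest

from nasift import detectors as det
from nasift.chem_perception import FeatureSet, shifted
from nasift.config import GeometryConfig
from nasift.errors import MissingHydrogenError
from nasift.fixtures import ProbeSpec, make_probe_complex, random_feature_scene
from nasift.geometry import random_rotation
from nasift.model_io import parse_ligands, parse_receptor, transform_ligand, transform_receptor

from conftest import donor, fa, feature_set, hexagon_ring
from oracles import ALL_CHANNELS, detector_for, oracle_keys


@pytest.fixture
def cfg():
    return GeometryConfig()


def record_keys(records):
    return {(r.receptor_side, r.ligand_side, r.mediator) for r in records}


class TestHydrogenBonds:
    @pytest.mark.parametrize("dist,n", [(3.0, 1), (3.9, 1), (3.91, 0), (5.0, 0)])
    def test_distance_cutoff_boundary(self, cfg, dist, n):
        rf = feature_set(hb_donors=[donor("D", (0, 0, 0), (1.0, 0, 0))])
        lf = feature_set(hb_acceptors=[fa("A", (dist, 0, 0))])
        assert len(det.detect_hydrogen_bonds(rf, lf, cfg)) == n

    @pytest.mark.parametrize("h,hits", [
        ((1.0, 0.0, 0.0), 1),    # D-H collinear with A: angle 180
        ((0.0, 1.0, 0.0), 0),    # angle 90 < 100 minimum
    ])
    def test_dha_angle_criterion(self, cfg, h, hits):
        rf = feature_set(hb_donors=[donor("D", (0, 0, 0), h)])
        lf = feature_set(hb_acceptors=[fa("A", (3.0, 0, 0))])
        recs = det.detect_hydrogen_bonds(rf, lf, cfg, mode="dha")
        assert len(recs) == hits
        if hits:
            assert recs[0].angle == pytest.approx(180.0)

    def test_dha_without_hydrogens_raises(self, cfg):
        rf = feature_set(hb_donors=[donor("D", (0, 0, 0))])
        lf = feature_set(hb_acceptors=[fa("A", (3.0, 0, 0))])
        with pytest.raises(MissingHydrogenError):
            det.detect_hydrogen_bonds(rf, lf, cfg, mode="dha")

    def test_both_directions_evaluated(self, cfg):
        rf = feature_set(hb_donors=[donor("rD", (0, 0, 0), (1, 0, 0))],
                         hb_acceptors=[fa("rA", (0, 5, 0))])
        lf = feature_set(hb_donors=[donor("lD", (0, 5, 3.0), (0, 5, 2.0))],
                         hb_acceptors=[fa("lA", (3.0, 0, 0))])
        recs = det.detect_hydrogen_bonds(rf, lf, cfg)
        assert record_keys(recs) == {("rD", "lA", ""), ("rA", "lD", "")}


class TestHalogenBonds:
    def ideal(self, cfg, dist=3.3, don=170.0, acc=120.0):
        a = np.radians(180.0 - don)
        c_pos = (dist + 1.77 * np.cos(a), 1.77 * np.sin(a), 0.0)
        b = np.radians(acc)
        y_pos = (1.4 * np.cos(b), 1.4 * np.sin(b), 0.0)
        lf = feature_set(halogen_donors=[(fa("C", c_pos, "C"), fa("X", (dist, 0, 0), "CL"))])
        rf = feature_set(hb_acceptors=[fa("A", (0, 0, 0), neighbors=(y_pos,))])
        return det.detect_halogen_bonds(rf, lf, cfg)

    def test_ideal_geometry_fires(self, cfg):
        assert len(self.ideal(cfg)) == 1

    def test_distance_beyond_cutoff(self, cfg):
        assert self.ideal(cfg, dist=4.5) == []

    def test_donor_angle_outside_window(self, cfg):
        assert self.ideal(cfg, don=90.0) == []

    def test_acceptor_angle_outside_window(self, cfg):
        assert self.ideal(cfg, acc=30.0) == []


class TestCationAnion:
    @pytest.mark.parametrize("dist,n", [(4.0, 1), (5.5, 1), (5.6, 0), (0.4, 0)])
    def test_distance_window(self, cfg, dist, n):
        rf = feature_set(anions=[fa("OP1", (0, 0, 0))])
        lf = feature_set(cations=[fa("N+", (dist, 0, 0), "N")])
        assert len(det.detect_cation_anion(rf, lf, cfg)) == n


class TestPiIon:
    def test_cation_on_normal_fires(self, cfg):
        rf = feature_set(rings=[hexagon_ring("ring", (0, 0, 0), (0, 0, 1))])
        lf = feature_set(cations=[fa("K+", (0, 0, 4.0), "K")])
        recs = det.detect_pi_ion(rf, lf, cfg, "cation")
        assert len(recs) == 1 and recs[0].subtype == "Pi-cation"

    def test_in_plane_ion_rejected(self, cfg):
        rf = feature_set(rings=[hexagon_ring("ring", (0, 0, 0), (0, 0, 1))])
        lf = feature_set(cations=[fa("K+", (4.0, 0, 0), "K")])
        assert det.detect_pi_ion(rf, lf, cfg, "cation") == []

    def test_ligand_ring_receptor_anion_direction(self, cfg):
        rf = feature_set(anions=[fa("OP1", (0, 0, 4.5))])
        lf = feature_set(rings=[hexagon_ring("benz", (0, 0, 0), (0, 0, 1))])
        recs = det.detect_pi_ion(rf, lf, cfg, "anion")
        assert len(recs) == 1 and recs[0].subtype == "Pi-anion"


class TestPiStacking:
    def stack(self, cfg, dz, offset=0.0, tilt=0.0):
        rf = feature_set(rings=[hexagon_ring("base", (0, 0, 0), (0, 0, 1))])
        tilt_n = (np.sin(np.radians(tilt)), 0.0, np.cos(np.radians(tilt)))
        lf = feature_set(rings=[hexagon_ring("benz", (offset, 0, dz), tilt_n)])
        return det.detect_pi_stacking(rf, lf, cfg)

    def test_parallel_zero_offset_is_sandwich(self, cfg):
        recs = self.stack(cfg, dz=3.5)
        assert [r.subtype for r in recs] == ["sandwich"]

    def test_parallel_with_offset_is_displaced(self, cfg):
        recs = self.stack(cfg, dz=3.5, offset=1.5)
        assert [r.subtype for r in recs] == ["parallel-displaced"]

    def test_distance_cutoff(self, cfg):
        assert self.stack(cfg, dz=8.0) == []

    def test_perpendicular_is_tshaped(self, cfg):
        recs = self.stack(cfg, dz=5.0, tilt=90.0)
        assert [r.subtype for r in recs] == ["T-shaped"]

    def test_intermediate_angle_rejected(self, cfg):
        assert self.stack(cfg, dz=3.5, tilt=45.0) == []


class TestMediated:
    def test_magnesium_bridge(self, cfg):
        rf = feature_set(hb_acceptors=[fa("OP1", (0, 0, 0))])
        lf = feature_set(hb_acceptors=[fa("O", (4.2, 0, 0))])
        ions = [fa("MG@1", (2.1, 0, 0), "MG")]
        recs = det.detect_ion_mediated(rf, lf, ions, cfg)
        assert [r.itype for r in recs] == ["Mg_mediated"]
        assert recs[0].distance == pytest.approx(2.1)

    def test_other_metal_routing(self, cfg):
        rf = feature_set(hb_acceptors=[fa("OP1", (0, 0, 0))])
        lf = feature_set(hb_acceptors=[fa("O", (4.2, 0, 0))])
        recs = det.detect_ion_mediated(rf, lf, [fa("ZN@1", (2.1, 0, 0), "ZN")], cfg)
        assert [r.itype for r in recs] == ["OtherMetal_mediated"]

    def test_long_ligand_leg_rejected(self, cfg):
        rf = feature_set(hb_acceptors=[fa("OP1", (0, 0, 0))])
        lf = feature_set(hb_acceptors=[fa("O", (6.1, 0, 0))])
        assert det.detect_ion_mediated(rf, lf, [fa("MG@1", (2.1, 0, 0), "MG")], cfg) == []

    def test_water_bridge(self, cfg):
        rf = feature_set(hb_acceptors=[fa("N3", (0, 0, 0), "N")])
        lf = feature_set(hb_donors=[donor("OH", (5.6, 0, 0), (5.0, 0, 0), "O")])
        recs = det.detect_water_mediated(rf, lf, [fa("HOH1", (2.8, 0, 0))], cfg)
        assert len(recs) == 1 and recs[0].mediator == "HOH1"

    def test_water_leg_beyond_cutoff(self, cfg):
        rf = feature_set(hb_acceptors=[fa("N3", (0, 0, 0), "N")])
        lf = feature_set(hb_acceptors=[fa("O", (6.4, 0, 0))])
        assert det.detect_water_mediated(rf, lf, [fa("HOH1", (3.6, 0, 0))], cfg) == []

    def test_no_waters_means_no_records(self, cfg):
        rf = feature_set(hb_acceptors=[fa("N3", (0, 0, 0), "N")])
        lf = feature_set(hb_acceptors=[fa("O", (2.0, 0, 0))])
        assert det.detect_water_mediated(rf, lf, [], cfg) == []


class TestLipophilicAndContact:
    @pytest.mark.parametrize("dist,n", [(3.8, 1), (4.0, 1), (4.1, 0)])
    def test_lipophilic_cutoff(self, cfg, dist, n):
        rf = feature_set(lipophilic=[fa("C5'", (0, 0, 0), "C")])
        lf = feature_set(lipophilic=[fa("C", (dist, 0, 0), "C")])
        assert len(det.detect_lipophilic(rf, lf, cfg)) == n

    def test_simple_and_pbs_bits(self, cfg):
        pdb, sdf = make_probe_complex(ProbeSpec("HB", 3.2), seed=0)
        rec = parse_receptor(pdb)
        lig = parse_ligands(sdf)[0]
        res = rec.residues[0]
        assert det.detect_contact(res, lig, cfg, "residue") == 1
        p, s, b = det.detect_contact(res, lig, cfg, "group")
        assert b == 1 and (p, s) == (0, 0)  # probe approaches the base face

    def test_far_ligand_all_zero(self, cfg):
        pdb, sdf = make_probe_complex(ProbeSpec("HB", 3.2), seed=0)
        rec = parse_receptor(pdb)
        lig = transform_ligand(parse_ligands(sdf)[0], np.eye(3), (50.0, 0.0, 0.0))
        res = rec.residues[0]
        assert det.detect_contact(res, lig, cfg, "residue") == 0
        assert det.detect_contact(res, lig, cfg, "group") == (0, 0, 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("channel", ALL_CHANNELS)
    def test_detectors_match_brute_force_scan(self, cfg, channel):
        run = detector_for(channel)
        fired = 0
        for seed in range(40):
            scene = random_feature_scene(seed)
            got = record_keys(run(scene, cfg))
            want = oracle_keys(channel, scene.residue_features, scene.ligand_features,
                               scene.waters, scene.ions, cfg)
            assert got == want, f"{channel} mismatch at seed {seed}"
            fired += len(want)
        assert fired > 0, f"{channel} never fired in 40 scenes"


class TestInvariances:
    def test_enlarging_cutoffs_is_monotone(self, cfg):
        wide = GeometryConfig(hb_dist_max=4.4, hal_dist_max=4.5, ca_dist_max=6.0,
                              pi_stack_dist_max=6.0, pi_ion_dist_max=6.5,
                              water_mediated_dist_max=4.0, lipophilic_dist_max=4.5)
        for seed in range(25):
            scene = random_feature_scene(seed + 1000)
            for channel in ALL_CHANNELS:
                run = detector_for(channel)
                assert record_keys(run(scene, cfg)) <= record_keys(run(scene, wide))

    def test_dha_subset_of_distance_only(self, cfg):
        for seed in range(25):
            scene = random_feature_scene(seed + 2000)
            dha = det.detect_hydrogen_bonds(scene.residue_features,
                                            scene.ligand_features, cfg, "dha")
            dist = det.detect_hydrogen_bonds(scene.residue_features,
                                             scene.ligand_features, cfg, "distance_only")
            assert record_keys(dha) <= record_keys(dist)

    def test_rigid_motion_preserves_records(self, cfg):
        pdb, sdf = make_probe_complex(ProbeSpec("PiStacking", 3.5, angle=0.0, offset=1.0),
                                      seed=7)
        rec = parse_receptor(pdb)
        lig = parse_ligands(sdf)[0]
        base = det.detect_all(rec, lig, cfg)
        rng = np.random.default_rng(11)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        moved = det.detect_all(transform_receptor(rec, R, t),
                               transform_ligand(lig, R, t), cfg)
        assert {r.key for r in base} == {r.key for r in moved}
        d1 = sorted(r.distance for r in base)
        d2 = sorted(r.distance for r in moved)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_duplicate_features_collapse(self, cfg):
        a = fa("A", (3.0, 0, 0))
        rf = feature_set(hb_donors=[donor("D", (0, 0, 0), (1, 0, 0))])
        lf = feature_set(hb_acceptors=[a, dataclasses.replace(a)])
        assert len(det.detect_hydrogen_bonds(rf, lf, cfg)) == 1
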