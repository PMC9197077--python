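"""Fingerprint assembly, wrappers, ion profiles and TSV round trips."""
import numpy as np
import pytest

from nasift.config import GeometryConfig
from nasift.detectors import FIXED_CHANNELS
from nasift.errors import EmptyReceptorError, ManifestError, NoIonsError, UsageError
from nasift.fingerprints import (
    SIFt,
    compute_sift,
    compute_sifts,
    detail_table_text,
    ion_profile,
    parse_sift_table,
    sift_table_text,
    wrap,
)
from nasift.fixtures import ProbeSpec, make_fingerprint_population, make_probe_complex
from nasift.model_io import Receptor, parse_ligands, parse_receptor, transform_ligand

from conftest import build_receptor


def probe_pair(itype="HB", distance=3.0, **kw):
    pdb, sdf = make_probe_complex(ProbeSpec(itype, distance, **kw), seed=0)
    return parse_receptor(pdb), parse_ligands(sdf)[0]


def synthetic_sift(bits, letters=("A", "C", "G", "U"), pose=1):
    manifest = tuple(("A", i + 1, l) for i, l in enumerate(letters))
    return SIFt(variant="FULL", residue_manifest=manifest, channels=FIXED_CHANNELS,
                bits=np.asarray(bits, dtype=np.uint8), ligand_id=("synthetic", pose))


class TestComputeSift:
    def test_full_vector_length_is_residues_times_channels(self):
        rec = build_receptor(["A", "C", "G"])
        _, sdf = make_probe_complex(ProbeSpec("HB", 3.0), seed=0)
        lig = transform_ligand(parse_ligands(sdf)[0], np.eye(3), (500.0, 0, 0))
        sift, _ = compute_sift(rec, lig, variant="FULL")
        assert len(sift.bits) == 3 * 12
        assert sift.channels == FIXED_CHANNELS

    def test_single_hydrogen_bond_sets_one_bit_at_the_right_offset(self):
        from nasift.model_io import transform_receptor

        rec, lig = probe_pair("HB", 3.0)
        # graft the probe's G (which holds the contact geometry) as residue 2,
        # shifted +50 x together with its ligand; residues 1 and 3 are remote
        moved = transform_receptor(rec, np.eye(3), (50.0, 0.0, 0.0))
        lig = transform_ligand(lig, np.eye(3), (50.0, 0.0, 0.0))
        rec3 = build_receptor(["A", "G", "U"], spacing=150.0)
        rec3.residues[1] = moved.residues[0].__class__(
            chain="A", number=2, name="G", atoms=moved.residues[0].atoms)
        rec3 = Receptor(residues=rec3.residues, waters=[], ions=[])
        sift, _ = compute_sift(rec3, lig, variant="FULL")
        assert sift.bits.sum() == 1
        assert sift.bits[1 * 12 + 0] == 1  # residue 2, channel HB

    def test_distant_ligand_gives_all_zero_vector(self):
        rec, lig = probe_pair("HB", 3.0)
        far = transform_ligand(lig, np.eye(3), (50.0, 0.0, 0.0))
        for variant in ("SIMPLE", "PBS", "FULL"):
            sift, _ = compute_sift(rec, far, variant=variant)
            assert sift.bits.sum() == 0

    def test_pbs_bit_implies_simple_bit(self):
        for itype, dist in (("Contact", 3.2), ("HB", 3.5), ("CationAnion", 4.0)):
            rec, lig = probe_pair(itype, dist)
            simple, _ = compute_sift(rec, lig, variant="SIMPLE")
            pbs, _ = compute_sift(rec, lig, variant="PBS")
            for i in range(len(rec.residues)):
                assert max(pbs.bits[3 * i:3 * i + 3]) <= simple.bits[i]

    def test_empty_receptor_raises(self):
        rec = Receptor(residues=[], waters=[], ions=[])
        _, lig = probe_pair()
        with pytest.raises(EmptyReceptorError):
            compute_sift(rec, lig)

    def test_waters_only_receptor_yields_empty_fingerprint(self):
        rec = build_receptor(["G"], waters=[(0.0, 0.0, 0.0)])
        rec = Receptor(residues=[], waters=rec.waters, ions=[])
        _, lig = probe_pair()
        sift, records = compute_sift(rec, lig)
        assert len(sift.bits) == 0 and records == []


class TestWrappers:
    def test_acug_or_aggregation(self):
        bits = np.zeros(4 * 12, dtype=np.uint8)
        bits[0 * 12 + 0] = 1   # HB on A1
        sift = synthetic_sift(bits, letters=("A", "C", "G", "A"))
        w = wrap(sift, "ACUG")
        values = dict(zip(w.labels, w.values))
        assert values["A#HB"] == 1
        assert values["C#HB"] == 0 and values["G#HB"] == 0 and values["U#HB"] == 0

    def test_counter_is_column_hamming_weight(self):
        bits = np.zeros(4 * 12, dtype=np.uint8)
        bits[0 * 12 + 0] = 1
        bits[3 * 12 + 0] = 1
        w = wrap(synthetic_sift(bits), "Counter")
        assert dict(zip(w.labels, w.values))["HB"] == 2

    def test_pupy_routes_purines(self):
        bits = np.zeros(4 * 12, dtype=np.uint8)
        bits[2 * 12 + 5] = 1   # PiStacking on G3
        w = wrap(synthetic_sift(bits), "PuPy")
        values = dict(zip(w.labels, w.values))
        assert values["Purine#PiStacking"] == 1
        assert values["Pyrimidine#PiStacking"] == 0

    def test_thymine_maps_to_u_slot(self):
        bits = np.zeros(4 * 12, dtype=np.uint8)
        bits[1 * 12 + 0] = 1
        sift = synthetic_sift(bits, letters=("A", "T", "G", "C"))
        values = dict(zip(*[wrap(sift, "ACUG").labels, wrap(sift, "ACUG").values]))
        assert values["U#HB"] == 1

    def test_conservation_on_random_fingerprints(self):
        for i, bits in enumerate(make_fingerprint_population(30, 0.3, 48, seed=5)):
            sift = synthetic_sift(bits, pose=i + 1)
            m = sift.channel_matrix()
            counter = wrap(sift, "Counter")
            np.testing.assert_array_equal(counter.values, m.sum(axis=0))
            acug = wrap(sift, "ACUG").values.reshape(4, 12)
            assert (acug.max(axis=0) == (m.max(axis=0) > 0)).all()
            # all-zero fingerprint implies all-zero wrappers
            if m.sum() == 0:
                assert counter.values.sum() == 0

    def test_unknown_wrapper_rejected(self):
        with pytest.raises(UsageError):
            wrap(synthetic_sift(np.zeros(48)), "Minmax")


class TestIonProfile:
    def test_ion_near_phosphate_sets_cation_anion_bit(self):
        pdb, _ = make_probe_complex(ProbeSpec("CationAnion", 3.0), seed=0)
        rec = parse_receptor(pdb)
        op1 = rec.residues[0].atom("OP1").xyz
        rec.ions.append(type(rec.residues[0].atoms[0])(
            serial=999, name="MG", element="MG", coords=tuple(op1 + [3.0, 0, 0])))
        profiles = ion_profile(rec)
        assert len(profiles) == 1
        sift = profiles[0]
        assert sift.bit(0, "CationAnion") == 1
        assert sift.bits.sum() == 1  # no other channel can fire for a bare cation

    def test_one_sift_per_ion(self):
        rec = build_receptor(["G"], ions=[("K", (0.0, 0.0, 9.0)), ("K", (0.0, 0.0, -9.0))])
        assert len(ion_profile(rec)) == 2

    def test_remote_ion_gives_all_zero(self):
        rec = build_receptor(["G"], ions=[("K", (100.0, 0.0, 0.0))])
        assert ion_profile(rec)[0].bits.sum() == 0

    def test_no_ions_raises(self):
        rec = build_receptor(["G"])
        with pytest.raises(NoIonsError):
            ion_profile(rec)


class TestTables:
    def test_sift_table_shape_and_round_trip(self):
        rec = build_receptor(["A", "C", "G"])
        _, sdf = make_probe_complex(ProbeSpec("HB", 3.0), seed=0)
        ligs = parse_ligands(sdf * 2)
        sifts, _ = compute_sifts(rec, ligs, variant="FULL")
        text = sift_table_text(sifts)
        lines = text.strip().splitlines()
        assert len(lines) == 3
        assert all(len(ln.split("\t")) == 1 + 36 for ln in lines)
        back = parse_sift_table(text)
        for s1, s2 in zip(sifts, back):
            np.testing.assert_array_equal(s1.bits, s2.bits)
            assert s1.residue_manifest == s2.residue_manifest
            assert s1.variant == s2.variant

    def test_empty_sift_list_gives_header_only(self):
        assert sift_table_text([]) == "ligand_id\n"

    def test_mixed_variants_rejected(self):
        rec, lig = probe_pair()
        s1, _ = compute_sift(rec, lig, variant="FULL")
        s2, _ = compute_sift(rec, lig, variant="SIMPLE")
        with pytest.raises(ManifestError):
            sift_table_text([s1, s2])

    def test_detail_formatting(self):
        rec, lig = probe_pair("HB", 2.85)
        _, records = compute_sift(rec, lig)
        text = detail_table_text(records)
        lines = text.strip().splitlines()
        row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
        assert row["distance"] == "2.850"
        assert row["interaction_type"] == "HB"
        assert row["residue_name"] == "G"

    def test_detail_ring_records_hold_centroids(self):
        rec, lig = probe_pair("PiStacking", 3.5, angle=0.0, offset=0.0)
        _, records = compute_sift(rec, lig)
        stack = [r for r in records if r.itype == "PiStacking"][0]
        assert stack.receptor_side.startswith("ring(")
        # centroid of the guanine six-ring, not an atom position
        np.testing.assert_allclose(stack.receptor_xyz, (0.0, 0.0, 0.0), atol=2e-3)

    def test_zero_records_header_only(self):
        text = detail_table_text([])
        assert len(text.strip().splitlines()) == 1
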