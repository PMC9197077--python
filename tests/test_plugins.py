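"""Plugin loading, evaluation, and cross-validation against built-ins."""
import numpy as np
import pytest

from nasift.chem_perception import DEFAULT_RULES
from nasift.config import GeometryConfig
from nasift.errors import PluginSchemaError
from nasift.fingerprints import compute_sift
from nasift.fixtures import ProbeSpec, make_probe_complex
from nasift.model_io import parse_ligands, parse_receptor
from nasift.plugins import evaluate_plugin, load_plugin_file, sample_plugin_text

from conftest import sdf_record

CFG = GeometryConfig()


def probe(itype="HB", distance=3.0, **kw):
    pdb, sdf = make_probe_complex(ProbeSpec(itype, distance, **kw), seed=0)
    return parse_receptor(pdb), parse_ligands(sdf)[0]


def hb_crosscheck_plugins(dmax=3.9):
    """Two directional distance-only plugins over the built-in donor/acceptor
    SMARTS; their OR must equal the built-in distance-only HB channel."""
    text = f"""
plugins:
  - name: hb_fwd
    receptor_smarts: "{DEFAULT_RULES.donor_smarts}"
    ligand_smarts: "{DEFAULT_RULES.acceptor_smarts}"
    distance: {{min: 0.0, max: {dmax}}}
  - name: hb_rev
    receptor_smarts: "{DEFAULT_RULES.acceptor_smarts}"
    ligand_smarts: "{DEFAULT_RULES.donor_smarts}"
    distance: {{min: 0.0, max: {dmax}}}
"""
    return load_plugin_file(text)


class TestLoading:
    def test_single_distance_plugin(self):
        defs = load_plugin_file(
            "plugins:\n"
            "  - name: close\n"
            "    receptor_smarts: '[*]'\n"
            "    ligand_smarts: '[*]'\n"
            "    distance: {max: 4.0}\n")
        assert len(defs) == 1 and defs[0].name == "close"
        assert defs[0].dmax == 4.0

    def test_duplicate_names_rejected(self):
        text = ("plugins:\n" + 2 * (
            "  - name: twin\n"
            "    receptor_smarts: '[*]'\n"
            "    ligand_smarts: '[*]'\n"
            "    distance: {max: 4.0}\n"))
        with pytest.raises(PluginSchemaError):
            load_plugin_file(text)

    def test_anchor_beyond_smarts_match_rejected(self):
        text = ("plugins:\n"
                "  - name: bad\n"
                "    receptor_smarts: '[#7]'\n"
                "    ligand_smarts: '[#8]'\n"
                "    distance: {max: 4.0}\n"
                "    angle: {min: 0, max: 90, atoms: [R1, L1, R3]}\n")
        with pytest.raises(PluginSchemaError):
            load_plugin_file(text)

    def test_invalid_smarts_rejected(self):
        text = ("plugins:\n"
                "  - name: broken\n"
                "    receptor_smarts: '[#6]('\n"
                "    ligand_smarts: '[*]'\n"
                "    distance: {max: 4.0}\n")
        with pytest.raises(PluginSchemaError):
            load_plugin_file(text)

    def test_missing_distance_rejected(self):
        text = ("plugins:\n"
                "  - name: nodist\n"
                "    receptor_smarts: '[*]'\n"
                "    ligand_smarts: '[*]'\n")
        with pytest.raises(PluginSchemaError):
            load_plugin_file(text)

    def test_sample_file_loads_six_plugins(self):
        defs = load_plugin_file(sample_plugin_text())
        assert [d.name for d in defs] == [
            "any", "polar", "weak_polar", "n_pi_star",
            "weak_hydrogen_bond", "halogen_multipolar"]


class TestEvaluation:
    def test_any_plugin_reproduces_simple_bits(self):
        any_plugin = load_plugin_file(
            "plugins:\n"
            "  - name: any\n"
            "    receptor_smarts: '[*]'\n"
            "    ligand_smarts: '[*]'\n"
            f"    distance: {{max: {CFG.simple_contact_dist_max}}}\n")
        for itype, dist in (("Contact", 3.2), ("HB", 3.0), ("Contact", 5.0)):
            rec, lig = probe(itype, dist)
            simple, _ = compute_sift(rec, lig, variant="SIMPLE")
            full, _ = compute_sift(rec, lig, variant="FULL", plugins=any_plugin)
            m = full.channel_matrix()
            plugin_bits = m[:, full.channels.index("any")]
            np.testing.assert_array_equal(plugin_bits, simple.bits)

    def test_polar_distance_plugin_fires(self):
        rec, lig = probe("HB", 3.0)
        defn = load_plugin_file(
            "plugins:\n"
            "  - name: polar\n"
            "    receptor_smarts: '[#7,#8]'\n"
            "    ligand_smarts: '[#7,#8]'\n"
            "    distance: {max: 3.9}\n")[0]
        recs = evaluate_plugin(defn, rec.residues[0], lig, CFG)
        assert any(r.receptor_side == "N7" for r in recs)

    def test_dihedral_window_rejects_out_of_window_geometry(self):
        # receptor O5'-P vs ligand C-O: construct a ligand whose O-C bond makes
        # a dihedral of about 90 degrees over the P-O5' axis; window [0, 10]
        rec, _ = probe("HB", 3.0)
        lig = parse_ligands(sdf_record(
            [("O", (5.0, 0.0, 0.0)), ("C", (5.0, 0.0, 1.4))], [(0, 1, 1)]))[0]
        defn = load_plugin_file(
            "plugins:\n"
            "  - name: dih\n"
            "    receptor_smarts: \"[OX2][P]\"\n"
            "    ligand_smarts: '[#8][#6]'\n"
            "    distance: {max: 50.0}\n"
            "    dihedral: {min: 0, max: 10, atoms: [R2, R1, L1, L2]}\n")[0]
        assert evaluate_plugin(defn, rec.residues[0], lig, CFG) == []

    def test_plugin_channels_do_not_alter_fixed_channels(self):
        rec, lig = probe("HB", 3.0)
        plain, _ = compute_sift(rec, lig, variant="FULL")
        with_plugins = compute_sift(rec, lig, variant="FULL",
                                    plugins=load_plugin_file(sample_plugin_text()))[0]
        n = len(rec.residues)
        fixed = with_plugins.channel_matrix()[:, :12]
        np.testing.assert_array_equal(fixed.ravel(), plain.bits.reshape(n, 12).ravel())

    def test_hb_crosscheck_on_probe_set(self):
        plugins = hb_crosscheck_plugins(dmax=CFG.hb_dist_max)
        for dist in (2.6, 3.0, 3.5, 3.9, 3.91, 4.5):
            rec, lig = probe("HB", dist)
            sift, _ = compute_sift(rec, lig, variant="FULL", plugins=plugins)
            m = sift.channel_matrix()
            hb = m[:, sift.channels.index("HB")]
            plugin_or = (m[:, sift.channels.index("hb_fwd")]
                         | m[:, sift.channels.index("hb_rev")])
            np.testing.assert_array_equal(hb, plugin_or)
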