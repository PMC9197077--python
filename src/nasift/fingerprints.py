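"""Assembly of detector output into structural interaction fingerprints (SIFts).

A SIFt is an ordered bit vector over (residue x channel).  Three resolutions
exist: SIMPLE (one any-contact bit per residue), PBS (three bits per residue,
for the phosphate / sugar / base fragments), and FULL (twelve typed channels
per residue: HB, HAL, CationAnion, PiCation, PiAnion, PiStacking, the four
metal-mediated channels, Water_mediated and Lipophilic; plugin channels are
appended after these in declaration order).

Three wrappers post-process a fingerprint: ACUG and PuPy OR-aggregate the
residue bits by nucleotide class, Counter sums them per channel.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import templates
from .chem_perception import DEFAULT_RULES, FeatureSet, PerceptionRules, ion_features
from .config import GeometryConfig
from .detectors import (
    FIXED_CHANNELS,
    InteractionRecord,
    detect_all,
    detect_cation_anion,
    detect_contact,
    receptor_features,
)
from .errors import EmptyReceptorError, ManifestError, NoIonsError, ParseError, UsageError
from .model_io import LigandRecord, Receptor

VARIANTS = ("SIMPLE", "PBS", "FULL")
SIMPLE_CHANNELS = ("Contact",)
PBS_CHANNELS = ("P", "S", "B")

WRAPPERS = ("ACUG", "PuPy", "Counter")
_ACUG_CLASSES = ("A", "C", "G", "U")  # T maps onto the U slot for DNA
_PUPY_CLASSES = ("Purine", "Pyrimidine")


@dataclass
class SIFt:
    """One fingerprint: bit vector over residue_manifest x channels."""
    variant: str
    residue_manifest: tuple[tuple[str, int, str], ...]
    channels: tuple[str, ...]
    bits: np.ndarray
    ligand_id: tuple[str, int]

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        expected = len(self.residue_manifest) * len(self.channels)
        if self.bits.shape != (expected,):
            raise ManifestError(
                f"bit vector length {self.bits.shape} != residues x channels = {expected}")

    def bit(self, residue_index: int, channel: str) -> int:
        return int(self.bits[residue_index * len(self.channels) + self.channels.index(channel)])

    def channel_matrix(self) -> np.ndarray:
        """(n_residues, n_channels) view of the bit vector."""
        return self.bits.reshape(len(self.residue_manifest), len(self.channels))

    @property
    def label(self) -> str:
        return f"{self.ligand_id[0] or 'ligand'}#{self.ligand_id[1]}"


@dataclass
class WrappedVector:
    wrapper: str
    labels: tuple[str, ...]
    values: np.ndarray


def channels_for(variant: str, plugin_names: tuple[str, ...] = ()) -> tuple[str, ...]:
    if variant == "SIMPLE":
        return SIMPLE_CHANNELS + tuple(plugin_names)
    if variant == "PBS":
        return PBS_CHANNELS + tuple(plugin_names)
    if variant == "FULL":
        return FIXED_CHANNELS + tuple(plugin_names)
    raise UsageError(f"unknown fingerprint variant {variant!r}")


# ---------------------------------------------------------------------------
# fingerprint computation
# ---------------------------------------------------------------------------


def compute_sift(receptor: Receptor, ligand: LigandRecord, variant: str = "FULL",
                 cfg: GeometryConfig | None = None, hb_mode: str = "distance_only",
                 rules: PerceptionRules = DEFAULT_RULES,
                 plugins=None) -> tuple[SIFt, list[InteractionRecord]]:
    """Compute one fingerprint (and its interaction records) for one pose.

    Returns ``(sift, records)``; for SIMPLE/PBS the records list is empty
    (those variants encode bare contacts, not typed interactions).
    """
    cfg = cfg or GeometryConfig()
    if not receptor.residues and not (receptor.waters or receptor.ions):
        raise EmptyReceptorError("receptor has no nucleotide residues")
    manifest = tuple(r.key for r in receptor.residues)
    plugin_names = tuple(p.name for p in plugins) if plugins else ()
    channels = channels_for(variant, plugin_names if variant == "FULL" else ())
    n_ch = len(channels)
    bits = np.zeros(len(manifest) * n_ch, dtype=np.uint8)
    row = {key: i for i, key in enumerate(manifest)}
    records: list[InteractionRecord] = []

    if variant == "SIMPLE":
        for i, res in enumerate(receptor.residues):
            bits[i] = detect_contact(res, ligand, cfg, granularity="residue")
    elif variant == "PBS":
        for i, res in enumerate(receptor.residues):
            p, s, b = detect_contact(res, ligand, cfg, granularity="group")
            bits[i * 3:(i + 1) * 3] = (p, s, b)
    else:
        records = detect_all(receptor, ligand, cfg, hb_mode=hb_mode, rules=rules)
        if plugins:
            from .plugins import evaluate_plugin  # deferred: plugins import us

            for defn in plugins:
                for res, _ in receptor_features(receptor, rules):
                    records += [
                        replace(r, ligand_title=ligand.title, pose=ligand.pose_index)
                        for r in evaluate_plugin(defn, res, ligand, cfg)
                    ]
        ch_index = {c: j for j, c in enumerate(channels)}
        for rec in records:
            j = ch_index.get(rec.itype)
            if j is not None and rec.residue in row:
                bits[row[rec.residue] * n_ch + j] = 1
    sift = SIFt(variant=variant, residue_manifest=manifest, channels=channels,
                bits=bits, ligand_id=(ligand.title, ligand.pose_index))
    return sift, records


def compute_sifts(receptor: Receptor, ligands: list[LigandRecord], **kwargs):
    """Fingerprints + pooled detail records for every pose in an SDF."""
    sifts, all_records = [], []
    for lig in ligands:
        s, recs = compute_sift(receptor, lig, **kwargs)
        sifts.append(s)
        all_records.extend(recs)
    return sifts, all_records


def ion_profile(receptor: Receptor, cfg: GeometryConfig | None = None,
                variant: str = "FULL",
                rules: PerceptionRules = DEFAULT_RULES) -> list[SIFt]:
    """Treat every inorganic ion of the receptor as a ligand, one SIFt each.

    For a bare metal cation the only FULL channel that can fire is
    CationAnion (SIMPLE/PBS give plain contact bits).
    """
    cfg = cfg or GeometryConfig()
    if not receptor.ions:
        raise NoIonsError("receptor contains no inorganic ions")
    manifest = tuple(r.key for r in receptor.residues)
    channels = channels_for(variant)
    n_ch = len(channels)
    sifts = []
    for k, ion in enumerate(ion_features(receptor.ions), 1):
        bits = np.zeros(len(manifest) * n_ch, dtype=np.uint8)
        pseudo = FeatureSet(cations=[ion])
        ion_xyz = ion.xyz
        for i, (res, rfeat) in enumerate(receptor_features(receptor, rules)):
            if variant == "FULL":
                recs = detect_cation_anion(rfeat, pseudo, cfg, residue_key=res.key)
                if recs:
                    bits[i * n_ch + channels.index("CationAnion")] = 1
            else:
                dmin = min(
                    (np.linalg.norm(a.xyz - ion_xyz) for a in res.atoms if not a.is_hydrogen),
                    default=np.inf)
                hit = int(dmin <= cfg.simple_contact_dist_max + 1e-9)
                if variant == "SIMPLE":
                    bits[i] = hit
                else:  # PBS: the ion contacts whichever fragment is nearest
                    for j, group_bit in enumerate(_pbs_ion_bits(res, ion_xyz, cfg)):
                        bits[i * 3 + j] = group_bit
        sifts.append(SIFt(variant=variant, residue_manifest=manifest, channels=channels,
                          bits=bits, ligand_id=(f"{ion.element}_{ion.index}", k)))
    return sifts


def _pbs_ion_bits(res, ion_xyz, cfg):
    from .model_io import Group

    bits = []
    for group in (Group.PHOSPHATE, Group.SUGAR, Group.BASE):
        atoms = [a for a in res.atoms
                 if not a.is_hydrogen and res.group_of.get(a.name) is group]
        dmin = min((np.linalg.norm(a.xyz - ion_xyz) for a in atoms), default=np.inf)
        bits.append(int(dmin <= cfg.simple_contact_dist_max + 1e-9))
    return bits


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------


def _residue_class(name: str, atoms_hint=None) -> str:
    letter = templates.canonical_letter(name) or templates.best_template(name, atoms_hint or [])
    if letter is None:
        raise UsageError(f"residue {name!r} has no nucleotide class")
    return "U" if letter == "T" else letter


def wrap(sift: SIFt, wrapper: str) -> WrappedVector:
    """Post-process a fingerprint with the ACUG / PuPy / Counter wrapper."""
    if wrapper not in WRAPPERS:
        raise UsageError(f"unknown wrapper {wrapper!r}; choose from {WRAPPERS}")
    matrix = sift.channel_matrix()
    if wrapper == "Counter":
        return WrappedVector(wrapper="Counter", labels=sift.channels,
                             values=matrix.sum(axis=0).astype(int))
    if wrapper == "ACUG":
        classes = _ACUG_CLASSES
        class_of = {key: _residue_class(key[2]) for key in sift.residue_manifest}
    else:
        classes = _PUPY_CLASSES
        class_of = {
            key: ("Purine" if _residue_class(key[2]) in ("A", "G") else "Pyrimidine")
            for key in sift.residue_manifest
        }
    values = np.zeros((len(classes), len(sift.channels)), dtype=int)
    for i, key in enumerate(sift.residue_manifest):
        ci = classes.index(class_of[key])
        values[ci] |= matrix[i].astype(int)
    labels = tuple(f"{cls}#{ch}" for cls in classes for ch in sift.channels)
    return WrappedVector(wrapper=wrapper, labels=labels, values=values.ravel())


# ---------------------------------------------------------------------------
# TSV output / input
# ---------------------------------------------------------------------------


def _column_name(key: tuple[str, int, str], channel: str) -> str:
    chain, number, name = key
    return f"{chain}.{number}.{name}#{channel}"


def sift_table_text(sifts: list[SIFt]) -> str:
    """TSV text: one row per ligand pose, one 0/1 column per (residue, channel)."""
    if sifts:
        ref = sifts[0]
        for s in sifts[1:]:
            if s.residue_manifest != ref.residue_manifest or s.channels != ref.channels \
                    or s.variant != ref.variant:
                raise ManifestError("fingerprints have mismatched manifests/variants")
        header = ["ligand_id"] + [_column_name(key, ch)
                                  for key in ref.residue_manifest for ch in ref.channels]
    else:
        header = ["ligand_id"]
    lines = ["\t".join(header)]
    for s in sifts:
        lines.append("\t".join([s.label] + [str(int(b)) for b in s.bits]))
    return "\n".join(lines) + "\n"


def write_sift_tsv(sifts: list[SIFt], path) -> None:
    with open(path, "w") as fh:
        fh.write(sift_table_text(sifts))


def parse_sift_table(text: str) -> list[SIFt]:
    """Re-read a fingerprint TSV into SIFt objects (bit-identical round trip)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty fingerprint table")
    header = lines[0].split("\t")
    if header[0] != "ligand_id":
        raise ParseError("fingerprint table must start with a ligand_id column")
    manifest: list[tuple[str, int, str]] = []
    channels: list[str] = []
    for col in header[1:]:
        try:
            residue_part, channel = col.rsplit("#", 1)
            chain, number, name = residue_part.split(".", 2)
        except ValueError as exc:
            raise ParseError(f"malformed fingerprint column {col!r}") from exc
        key = (chain, int(number), name)
        if not manifest or manifest[-1] != key:
            manifest.append(key)
        if len(manifest) == 1:
            channels.append(channel)
    chans = tuple(channels)
    if len(header) - 1 != len(manifest) * len(chans):
        raise ParseError("fingerprint table columns are not residue x channel shaped")
    if chans == SIMPLE_CHANNELS:
        variant = "SIMPLE"
    elif chans == PBS_CHANNELS:
        variant = "PBS"
    else:
        variant = "FULL"
    sifts = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        label = fields[0]
        title, _, pose = label.rpartition("#")
        bits = np.array([int(v) for v in fields[1:]], dtype=np.uint8)
        sifts.append(SIFt(variant=variant, residue_manifest=tuple(manifest),
                          channels=chans, bits=bits,
                          ligand_id=(title, int(pose) if pose.isdigit() else 0)))
    return sifts


def read_sift_tsv(path) -> list[SIFt]:
    with open(path) as fh:
        return parse_sift_table(fh.read())


def wrapped_table_text(wrapped: list[WrappedVector], ids: list[str]) -> str:
    if not wrapped:
        return "ligand_id\n"
    labels = wrapped[0].labels
    lines = ["\t".join(["ligand_id"] + list(labels))]
    for wid, w in zip(ids, wrapped):
        if w.labels != labels:
            raise ManifestError("wrapped vectors have mismatched labels")
        lines.append("\t".join([wid] + [str(int(v)) for v in w.values]))
    return "\n".join(lines) + "\n"


_DETAIL_COLUMNS = ("ligand_title", "pose", "interaction_type", "subtype", "chain",
                   "residue_number", "residue_name", "receptor_atoms", "receptor_xyz",
                   "ligand_atoms", "ligand_xyz", "mediator", "distance", "angle")


def _fmt_xyz(xyz) -> str:
    return ",".join(f"{v:.3f}" for v in xyz)


def detail_table_text(records: list[InteractionRecord],
                      channel_order: tuple[str, ...] = FIXED_CHANNELS) -> str:
    """Human-readable TSV listing of all detected interactions.

    Rows are ordered by pose, then residue number, then channel; distances and
    angles are printed with three decimals; ring partners are reported by
    their centroid coordinates.
    """
    order = {c: i for i, c in enumerate(channel_order)}
    rows = sorted(records, key=lambda r: (r.pose, r.residue[1],
                                          order.get(r.itype, len(order)), r.itype,
                                          r.receptor_side, r.ligand_side, r.mediator))
    lines = ["\t".join(_DETAIL_COLUMNS)]
    for r in rows:
        lines.append("\t".join([
            r.ligand_title, str(r.pose), r.itype, r.subtype,
            r.residue[0], str(r.residue[1]), r.residue[2],
            r.receptor_side, _fmt_xyz(r.receptor_xyz),
            r.ligand_side, _fmt_xyz(r.ligand_xyz),
            r.mediator, f"{r.distance:.3f}",
            "" if r.angle is None else f"{r.angle:.3f}",
        ]))
    return "\n".join(lines) + "\n"


def write_detail_tsv(records: list[InteractionRecord], path,
                     channel_order: tuple[str, ...] = FIXED_CHANNELS) -> None:
    with open(path, "w") as fh:
        fh.write(detail_table_text(records, channel_order))
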