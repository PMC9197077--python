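"""Interaction hot-spot statistics over pooled detail records.

Aggregates the per-interaction detail listings of one or many complexes into
the survey-style statistics: counts and percentages per receptor atom and
interaction type, phosphate/sugar/base roll-ups, nucleobase-face assignment
of hydrogen-bond partners (Watson-Crick / Hoogsteen / sugar edge),
unique-residue interaction counts and bond-length histograms.

Input is either a list of :class:`~nasift.detectors.InteractionRecord` or a
pandas DataFrame with the detail-TSV columns; a ``complex`` column (source
structure id) may be added when pooling several complexes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import templates
from .config import GeometryConfig
from .errors import FaceError
from .model_io import Group

#: default nucleobase face assignment of the hydrogen-bond-capable base
#: atoms.  Atoms shared between two edges are assigned to the single face
#: consistent with the observed interaction trends (guanine O6/N7 Hoogsteen,
#: the amino/imino Watson-Crick groups); user-overridable.
DEFAULT_FACE_MAP: dict[str, dict[str, str]] = {
    "A": {"N1": "WatsonCrick", "N6": "WatsonCrick", "N7": "Hoogsteen", "N3": "Sugar"},
    "G": {"N1": "WatsonCrick", "N2": "WatsonCrick", "O6": "Hoogsteen",
          "N7": "Hoogsteen", "N3": "Sugar"},
    "C": {"N3": "WatsonCrick", "N4": "WatsonCrick", "O2": "Sugar"},
    "U": {"N3": "WatsonCrick", "O4": "WatsonCrick", "O2": "Sugar"},
    "T": {"N3": "WatsonCrick", "O4": "WatsonCrick", "O2": "Sugar"},
}

FACES = ("WatsonCrick", "Hoogsteen", "Sugar")


def records_frame(records) -> pd.DataFrame:
    """Normalize records (objects or a detail DataFrame) to a DataFrame."""
    columns = ["ligand_title", "pose", "interaction_type", "subtype", "chain",
               "residue_number", "residue_name", "receptor_atoms", "ligand_atoms",
               "mediator", "distance", "angle"]
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    elif not records:
        df = pd.DataFrame(columns=columns)
    else:
        df = pd.DataFrame([{
            "ligand_title": r.ligand_title, "pose": r.pose,
            "interaction_type": r.itype, "subtype": r.subtype,
            "chain": r.residue[0], "residue_number": r.residue[1],
            "residue_name": r.residue[2], "receptor_atoms": r.receptor_side,
            "ligand_atoms": r.ligand_side, "mediator": r.mediator,
            "distance": r.distance,
            "angle": np.nan if r.angle is None else r.angle,
        } for r in records])
    if "complex" not in df.columns:
        df["complex"] = ""
    return df


def atom_interaction_stats(records) -> pd.DataFrame:
    """Counts per (residue_name, atom_name, interaction type) with percentages.

    ``pct_of_type`` normalizes within each interaction type (sums to 100 per
    type), ``pct_of_residue`` within each (residue_name, type) pair.  Ring
    partners are counted under their ring label.
    """
    df = records_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["residue_name", "atom_name", "interaction_type",
                                     "count", "pct_of_type", "pct_of_residue"])
    grouped = (df.groupby(["residue_name", "receptor_atoms", "interaction_type"])
                 .size().rename("count").reset_index()
                 .rename(columns={"receptor_atoms": "atom_name"}))
    type_totals = grouped.groupby("interaction_type")["count"].transform("sum")
    res_totals = grouped.groupby(["residue_name", "interaction_type"])["count"].transform("sum")
    grouped["pct_of_type"] = 100.0 * grouped["count"] / type_totals
    grouped["pct_of_residue"] = 100.0 * grouped["count"] / res_totals
    return grouped.sort_values(["interaction_type", "count"],
                               ascending=[True, False]).reset_index(drop=True)


def group_rollup(records) -> pd.DataFrame:
    """Percentage of each interaction type carried by phosphate/sugar/base atoms.

    Ring-partner records (centroid labels) count as BASE.
    """
    df = records_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["interaction_type", "group", "count", "pct"])

    def group_of(atom_name: str) -> str:
        if atom_name.startswith("ring("):
            return Group.BASE.value
        if atom_name in templates.PHOSPHATE_ATOMS:
            return Group.PHOSPHATE.value
        if atom_name in templates.SUGAR_ATOMS:
            return Group.SUGAR.value
        return Group.BASE.value

    df = df.assign(group=df["receptor_atoms"].map(group_of))
    out = df.groupby(["interaction_type", "group"]).size().rename("count").reset_index()
    totals = out.groupby("interaction_type")["count"].transform("sum")
    out["pct"] = 100.0 * out["count"] / totals
    return out


def face_of(base_letter: str, atom_name: str,
            facemap: dict[str, dict[str, str]] | None = None) -> str:
    """Watson-Crick / Hoogsteen / Sugar face of a base hydrogen-bond partner."""
    facemap = facemap or DEFAULT_FACE_MAP
    letter = templates.canonical_letter(base_letter) or base_letter
    try:
        return facemap[letter][atom_name]
    except KeyError as exc:
        raise FaceError(f"atom {atom_name!r} of base {base_letter!r} has no face "
                        "assignment") from exc


def face_stats(records, facemap=None) -> pd.DataFrame:
    """Per-base percentages of hydrogen bonds on each nucleobase face.

    Only hydrogen-bond records whose receptor atom is in the face map are
    counted (backbone and unmapped atoms are outside the base edges).
    """
    df = records_frame(records)
    df = df[df["interaction_type"] == "HB"]
    rows = []
    for _, r in df.iterrows():
        try:
            face = face_of(r["residue_name"], r["receptor_atoms"], facemap)
        except FaceError:
            continue
        letter = templates.canonical_letter(r["residue_name"]) or r["residue_name"]
        rows.append((letter, face))
    if not rows:
        return pd.DataFrame(columns=["base", "face", "count", "pct_of_base"])
    out = (pd.DataFrame(rows, columns=["base", "face"])
             .groupby(["base", "face"]).size().rename("count").reset_index())
    totals = out.groupby("base")["count"].transform("sum")
    out["pct_of_base"] = 100.0 * out["count"] / totals
    return out


def unique_residue_counts(records) -> pd.Series:
    """Per interaction type: number of distinct (complex, chain, residue number)
    residues forming at least one such interaction."""
    df = records_frame(records)
    if df.empty:
        return pd.Series(dtype=int, name="unique_residues")
    out = (df.drop_duplicates(["interaction_type", "complex", "chain", "residue_number"])
             .groupby("interaction_type").size())
    out.name = "unique_residues"
    return out


def interaction_counts(records) -> pd.Series:
    """Raw record counts per interaction type."""
    df = records_frame(records)
    if df.empty:
        return pd.Series(dtype=int, name="count")
    out = df.groupby("interaction_type").size()
    out.name = "count"
    return out


#: distance ranges per built-in type for histogramming: (min cutoff, max-cutoff attr)
_RANGE_OF = {
    "HB": (0.0, "hb_dist_max"),
    "HAL": (0.0, "hal_dist_max"),
    "CationAnion": ("ca_dist_min", "ca_dist_max"),
    "PiCation": (0.0, "pi_ion_dist_max"),
    "PiAnion": (0.0, "pi_ion_dist_max"),
    "PiStacking": (0.0, "pi_stack_dist_max"),
    "Water_mediated": (0.0, "water_mediated_dist_max"),
    "Lipophilic": (0.0, "lipophilic_dist_max"),
}


def distance_histogram(records, itype: str, bin_width: float = 0.2,
                       cfg: GeometryConfig | None = None):
    """Histogram of bond lengths for one interaction type.

    Bins span the configured [min cutoff, max cutoff] range of the type
    (0 to the largest coordination cutoff for the mediated channels); the
    default bin width is 0.2 A.  Returns ``(bin_edges, counts)`` with total
    count conserved.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cfg = cfg or GeometryConfig()
    df = records_frame(records)
    values = df.loc[df["interaction_type"] == itype, "distance"].to_numpy(float)
    lo, hi_attr = _RANGE_OF.get(itype, (0.0, "simple_contact_dist_max"))
    if itype.endswith("_mediated") and itype != "Water_mediated":
        lo, hi = 0.0, max(cfg.ion_mediated_dist_max.values())
    else:
        lo = getattr(cfg, lo) if isinstance(lo, str) else lo
        hi = getattr(cfg, hi_attr)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.clip(values, lo, edges[-1] - 1e-12), bins=edges)
    return edges, counts


def histogram_table_text(edges: np.ndarray, counts: np.ndarray) -> str:
    lines = ["bin_start\tbin_end\tcount"]
    for lo, hi, c in zip(edges[:-1], edges[1:], counts):
        lines.append(f"{lo:.3f}\t{hi:.3f}\t{int(c)}")
    return "\n".join(lines) + "\n"
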