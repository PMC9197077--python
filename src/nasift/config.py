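"""Geometric criteria used by the interaction detectors.

Only the 3.9 A hydrogen-bond distance cutoff is fixed by the original method
description; the remaining defaults reconstruct the usual literature values
(PLIP-style donor angle, Auffinger-style halogen windows, classic stacking
criteria, 3.5 A water coordination legs, 4.0 A lipophilic contacts).  Every
value can be overridden from a flat ``key = value`` config file, which is a
stated design requirement of the method.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ParseError, UsageError

#: per-element coordination cutoffs (A) for metal-mediated interactions
DEFAULT_ION_CUTOFFS = {"MG": 3.0, "K": 3.5, "NA": 3.1, "other": 3.0}


@dataclass
class GeometryConfig:
    """All numeric criteria used by any detector.  Distances in A, angles in degrees."""

    hb_dist_max: float = 3.9          #: donor heavy atom ... acceptor
    hb_dha_angle_min: float = 100.0   #: D-H...A angle lower bound (dha mode)
    hal_dist_max: float = 4.0         #: halogen X ... acceptor
    hal_don_angle: float = 165.0      #: ideal C-X...A angle
    hal_don_angle_window: float = 30.0
    hal_acc_angle: float = 120.0      #: ideal X...A-Y angle
    hal_acc_angle_window: float = 30.0
    ca_dist_min: float = 0.5          #: cation-anion clash guard
    ca_dist_max: float = 5.5
    pi_stack_dist_max: float = 5.5    #: ring centroid ... ring centroid
    pi_stack_offset_max: float = 2.0
    pi_stack_parallel_angle_max: float = 30.0
    pi_stack_tshape_angle_min: float = 60.0
    pi_stack_tshape_angle_max: float = 90.0
    pi_stack_sandwich_offset: float = 0.5   #: offset below which a parallel stack is a sandwich
    pi_ion_dist_max: float = 6.0      #: ring centroid ... charged atom
    pi_ion_angle_max: float = 30.0    #: angle to the ring normal
    ion_mediated_dist_max: dict = field(default_factory=lambda: dict(DEFAULT_ION_CUTOFFS))
    water_mediated_dist_max: float = 3.5
    lipophilic_dist_max: float = 4.0
    simple_contact_dist_max: float = 4.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and "angle" not in f.name and v <= 0:
                if f.name != "ca_dist_min":  # ca_dist_min = 0 would be legal but is > 0 by default
                    raise UsageError(f"{f.name} must be positive, got {v}")
        if not self.ca_dist_min < self.ca_dist_max:
            raise UsageError("ca_dist_min must be smaller than ca_dist_max")
        if any(v <= 0 for v in self.ion_mediated_dist_max.values()):
            raise UsageError("ion coordination cutoffs must be positive")
        if "other" not in self.ion_mediated_dist_max:
            raise UsageError("ion_mediated_dist_max needs an 'other' fallback entry")

    def ion_cutoff(self, element: str) -> float:
        e = element.upper()
        return self.ion_mediated_dist_max.get(e, self.ion_mediated_dist_max["other"])

    # -- flat key=value round trip -------------------------------------------

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dict):
                v = ",".join(f"{k}:{val}" for k, val in v.items())
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GeometryConfig":
        """Parse a flat ``key = value`` file; unknown keys are an error."""
        names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"config line {lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key not in names:
                raise ParseError(f"config line {lineno}: unknown key {key!r}")
            if key == "ion_mediated_dist_max":
                entries = {}
                for item in val.split(","):
                    k, _, v = item.partition(":")
                    if not v:
                        raise ParseError(f"config line {lineno}: bad ion cutoff {item!r}")
                    entries[k.strip().upper() if k.strip().lower() != "other" else "other"] = float(v)
                kwargs[key] = entries
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)
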