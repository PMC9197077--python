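"""Exception hierarchy.

All package errors derive from :class:`NasiftError` so callers can catch one
base class; the CLI maps subfamilies to exit codes (parse errors -> 3,
chemistry/geometry errors -> 4).
"""


class NasiftError(Exception):
    """Base class for all nasift errors."""


# --- input / parsing ---------------------------------------------------------

class ParseError(NasiftError):
    """Malformed or empty PDB/SDF/TSV input."""


class UniqueNumberingError(ParseError):
    """Two receptor residues share the same residue number."""


class UnsupportedResidueError(ParseError):
    """Residue is neither a nucleotide, water, nor an inorganic ion."""


class UnclassifiableAtomError(ParseError):
    """Atom name matches no phosphate/sugar/base classification rule."""


class ManifestError(ParseError):
    """Fingerprints with incompatible residue manifests or variants."""


# --- chemistry / geometry ----------------------------------------------------

class ChemistryError(NasiftError):
    """Base class for perception/geometry failures."""


class SanitizationError(ChemistryError):
    """Molecule cannot be sanitized (e.g. impossible valence for the charge)."""


class PatternError(ChemistryError):
    """Invalid SMARTS pattern."""


class GeometryError(ChemistryError):
    """Degenerate geometry (e.g. collinear ring atoms)."""


class MissingHydrogenError(ChemistryError):
    """D-H...A hydrogen-bond mode requested but a donor carries no hydrogen."""


class EmptyReceptorError(ChemistryError):
    """Receptor contains no nucleotide residues."""


class NoIonsError(ChemistryError):
    """Ion-profile mode requested on a receptor without inorganic ions."""


class FaceError(ChemistryError):
    """Base atom not present in the nucleobase face map."""


# --- similarity --------------------------------------------------------------

class LengthError(NasiftError):
    """Bit vectors of unequal length."""


# --- plugins -----------------------------------------------------------------

class PluginSchemaError(NasiftError):
    """Plugin YAML violates the documented schema."""


# --- fixtures ----------------------------------------------------------------

class SpecError(NasiftError):
    """Probe specification is unrealizable."""


class UsageError(NasiftError):
    """Invalid argument combination (unknown wrapper, metric, ...)."""
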