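"""Similarity and distance metrics for binary interaction fingerprints.

Eight metrics over bit vectors a, b with counts A = |a|, B = |b| and
C = |a AND b|::

    Tanimoto            C / (A + B - C)
    Tversky(alpha,beta) C / (C + alpha (A - C) + beta (B - C))
    Cosine              C / sqrt(A B)
    Manhattan           A + B - 2 C
    Euclidean           sqrt(A + B - 2 C)
    SquareEuclidean     A + B - 2 C
    HalfSquareEuclidean (A + B - 2 C) / 2
    Soergel             (A + B - 2 C) / (A + B - C)

Tversky's first argument is the *reference*: with the customary alpha = 1,
beta = 0 it is the fraction of the reference's interactions recapitulated in
the model.  The 0/0 case (two all-zero fingerprints under Tanimoto, Cosine,
Tversky, Soergel) is defined as 0 with a warning, since ligands far from the
receptor legitimately produce empty fingerprints.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import LengthError, ManifestError, UsageError

METRIC_NAMES = ("Tanimoto", "Cosine", "Manhattan", "Euclidean",
                "SquareEuclidean", "HalfSquareEuclidean", "Soergel", "Tversky")


@dataclass(frozen=True)
class MetricSpec:
    name: str
    alpha: float = 1.0  # Tversky only
    beta: float = 0.0   # Tversky only

    def __post_init__(self):
        if self.name not in METRIC_NAMES:
            raise UsageError(f"unknown metric {self.name!r}; choose from {METRIC_NAMES}")
        if self.alpha < 0 or self.beta < 0:
            raise UsageError("Tversky alpha/beta must be non-negative")


def bit_counts(a, b) -> tuple[int, int, int]:
    """(A, B, C) = set bits of a, of b, and of their intersection."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise LengthError(f"fingerprint lengths differ: {a.size} vs {b.size}")
    return int(a.sum()), int(b.sum()), int((a & b).sum())


def _zero_over_zero(name: str) -> float:
    warnings.warn(f"{name} of two all-zero fingerprints defined as 0", stacklevel=3)
    return 0.0


def metric(a, b, spec: MetricSpec) -> float:
    """Evaluate one metric on a pair of equal-length binary vectors.

    For Tversky, ``a`` is the reference fingerprint.
    """
    A, B, C = bit_counts(a, b)
    d = A + B - 2 * C
    if spec.name == "Tanimoto":
        return C / (A + B - C) if A + B - C else _zero_over_zero("Tanimoto")
    if spec.name == "Tversky":
        denom = C + spec.alpha * (A - C) + spec.beta * (B - C)
        return C / denom if denom else _zero_over_zero("Tversky")
    if spec.name == "Cosine":
        return C / np.sqrt(A * B) if A and B else _zero_over_zero("Cosine")
    if spec.name == "Manhattan":
        return float(d)
    if spec.name == "Euclidean":
        return float(np.sqrt(d))
    if spec.name == "SquareEuclidean":
        return float(d)
    if spec.name == "HalfSquareEuclidean":
        return d / 2.0
    if spec.name == "Soergel":
        return d / (A + B - C) if A + B - C else _zero_over_zero("Soergel")
    raise UsageError(f"unknown metric {spec.name!r}")  # unreachable


def distance_matrix(sifts, spec: MetricSpec) -> tuple[list[str], np.ndarray]:
    """All-vs-all metric matrix over fingerprints (or raw bit vectors).

    Accepts :class:`~nasift.fingerprints.SIFt` objects (their manifests must
    agree) or plain vectors.  The matrix row index is the Tversky reference.
    """
    labels, vectors = [], []
    manifest = None
    for i, s in enumerate(sifts):
        if hasattr(s, "bits"):
            if manifest is not None and (s.residue_manifest, s.channels) != manifest:
                raise ManifestError("fingerprints have mismatched manifests")
            manifest = (s.residue_manifest, s.channels)
            labels.append(s.label)
            vectors.append(np.asarray(s.bits))
        else:
            labels.append(f"v{i + 1}")
            vectors.append(np.asarray(s))
    n = len(vectors)
    out = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(n):
                out[i, j] = metric(vectors[i], vectors[j], spec)
    return labels, out


def matrix_table_text(labels: list[str], matrix: np.ndarray) -> str:
    lines = ["\t".join([""] + labels)]
    for lbl, row in zip(labels, matrix):
        lines.append("\t".join([lbl] + [f"{v:.6g}" for v in row]))
    return "\n".join(lines) + "\n"


def write_matrix_tsv(labels: list[str], matrix: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write(matrix_table_text(labels, matrix))
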