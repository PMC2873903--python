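"""Peptide-level structural descriptors of motif-likeness.

Bound linear motifs tend to be flat and stretched compared to other
peptides of the same length. Two scalar descriptors capture this:
*elongation*, the distance between the first and last Cα, and *linearity*,
the maximum deviation of any interior Cα from the line through the first
and last Cα (small = flat). Together with the modal DSSP class, mean
accessibility and residue count they form the feature vector a linear SVM
separates motif-like from globular peptides with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import DSSP_CLASSES

__all__ = [
    "PeptideFeatures",
    "elongation",
    "linearity",
    "peptide_ss_class",
    "peptide_accessibility",
    "encode_features",
    "FeatureScaler",
    "N_FEATURES",
]

# tie-break priority for the modal DSSP class: strong regular classes first
SS_PRIORITY = "HEGIBTS-"

N_FEATURES = 4 + len(DSSP_CLASSES)  # length, elongation, linearity, accessibility + one-hot SS


@dataclass(frozen=True)
class PeptideFeatures:
    length: int          # residue count, 4–20
    elongation: float    # Å
    linearity: float     # Å
    ss_class: str        # modal DSSP letter
    accessibility: float # mean Å² per residue

    def __post_init__(self) -> None:
        if not 4 <= self.length <= 20:
            raise ValueError(f"peptide length {self.length} outside 4–20")
        if self.elongation < 0 or self.linearity < 0:
            raise ValueError("elongation and linearity must be non-negative")
        if self.ss_class not in DSSP_CLASSES:
            raise ValueError(f"unknown DSSP class {self.ss_class!r}")


def elongation(ca_coords: np.ndarray) -> float:
    """Distance between the first and last Cα (Å)."""
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        raise ValueError("elongation requires at least 2 Cα coordinates")
    return float(np.linalg.norm(coords[-1] - coords[0]))


def linearity(ca_coords: np.ndarray) -> float:
    """Maximum deviation of any Cα from the first-to-last Cα line (Å).

    A low value indicates a flat, linear peptide. Undefined (error) when
    the terminal Cα coincide: a closed hairpin has no axis and must not be
    mistaken for a linear peptide.
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 3:
        raise ValueError("linearity requires at least 3 Cα coordinates")
    axis = coords[-1] - coords[0]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("first and last Cα coincide; linearity undefined")
    u = axis / norm
    rel = coords[1:-1] - coords[0]
    perp = rel - np.outer(rel @ u, u)
    return float(np.sqrt((perp**2).sum(axis=1)).max())


def peptide_ss_class(residue_classes: list[str]) -> str:
    """Modal DSSP class; ties broken by the fixed priority H>E>G>I>B>T>S>-."""
    if not residue_classes:
        raise ValueError("empty secondary-structure list")
    for c in residue_classes:
        if c not in DSSP_CLASSES:
            raise ValueError(f"unknown DSSP class {c!r}")
    counts = {c: residue_classes.count(c) for c in set(residue_classes)}
    best = max(counts.values())
    return min((c for c, n in counts.items() if n == best), key=SS_PRIORITY.index)


def peptide_accessibility(residue_access: list[float]) -> float:
    """Arithmetic mean of per-residue accessibility (Å²)."""
    if not residue_access:
        raise ValueError("empty accessibility list")
    for i, a in enumerate(residue_access):
        if a is None:
            raise ValueError(f"residue {i + 1}: accessibility undefined")
        if a < 0:
            raise ValueError(f"residue {i + 1}: negative accessibility")
    return float(np.mean(residue_access))


@dataclass
class FeatureScaler:
    """z-score standardization statistics, stored with the trained model."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # constant columns pass through unscaled
        return cls(mean=X.mean(axis=0), sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.sd + self.mean


def encode_features(f: PeptideFeatures) -> np.ndarray:
    """Raw 12-dim vector: [length, elongation, linearity, accessibility,
    one-hot DSSP class over the 8-letter alphabet]."""
    vec = np.zeros(N_FEATURES)
    vec[0] = f.length
    vec[1] = f.elongation
    vec[2] = f.linearity
    vec[3] = f.accessibility
    vec[4 + DSSP_CLASSES.index(f.ss_class)] = 1.0
    return vec


def features_from_residues(residues) -> PeptideFeatures:
    """Convenience: compute PeptideFeatures from a residue window."""
    cas = [r.ca for r in residues]
    if any(c is None for c in cas):
        raise ValueError("peptide window contains residues without Cα")
    coords = np.asarray(cas)
    return PeptideFeatures(
        length=len(residues),
        elongation=elongation(coords),
        linearity=linearity(coords),
        ss_class=peptide_ss_class([r.ss_class for r in residues]),
        accessibility=peptide_accessibility([r.accessibility for r in residues]),
    )
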