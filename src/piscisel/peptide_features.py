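"""Peptide-level analytics for antimicrobial peptides: amino acid
composition, percent-identity matrices, Schiffer-Edmundson helical
wheel projection and the hydrophobic moment mu_H.

The wheel places residue k (1-based) at ((k-1) * 100) degrees — the
ideal alpha-helix advance per residue — and mu_H is the length of the
vector sum of per-residue hydrophobicities around the wheel, divided by
the peptide length so peptides of different lengths are comparable.
"""

from __future__ import annotations

import cmath
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Eisenberg consensus hydrophobicity scale (default; any residue->value
#: mapping can be supplied instead)
EISENBERG_CONSENSUS: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HYDROPHILIC_CHARGED = frozenset("DEKRH")
VERY_HYDROPHOBIC = frozenset("FILMVW")

WHEEL_STEP_DEG = 100.0


def _check_peptide(peptide: str) -> str:
    peptide = peptide.upper()
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residue letter(s): {sorted(bad)}")
    return peptide


def composition(peptide: str) -> dict[str, float]:
    """Fraction of each amino acid present; fractions sum to 1."""
    peptide = _check_peptide(peptide)
    if not peptide:
        raise ValueError("empty peptide")
    counts = Counter(peptide)
    n = len(peptide)
    return {aa: c / n for aa, c in sorted(counts.items())}


def pairwise_identity(peptides: dict[str, str] | list[str],
                      denominator: str = "overlap") -> "IdentityMatrix":
    """Percent-identity matrix of aligned peptides.

    ``denominator='overlap'`` (BioEdit-style, default) counts only columns
    where both rows are non-gap; ``'alignment'`` divides by the full
    alignment length instead.
    """
    if isinstance(peptides, dict):
        labels = list(peptides)
        rows = [peptides[k] for k in labels]
    else:
        labels = [f"seq{i + 1}" for i in range(len(peptides))]
        rows = list(peptides)
    if len({len(r) for r in rows}) > 1:
        raise ValueError("aligned peptides must have equal length")
    if denominator not in ("overlap", "alignment"):
        raise ValueError("denominator must be 'overlap' or 'alignment'")
    n = len(rows)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if denominator == "overlap":
                if not both:
                    raise ValueError(
                        f"no overlapping residues between {labels[i]} and {labels[j]}"
                    )
                denom = len(both)
            else:
                denom = len(a)
            ident = sum(1 for x, y in both if x == y)
            mat[i, j] = mat[j, i] = 100.0 * ident / denom
    return IdentityMatrix(labels, mat)


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def off_diagonal(self) -> np.ndarray:
        n = len(self.labels)
        iu = np.triu_indices(n, 1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Helical wheel
# ---------------------------------------------------------------------------

@dataclass
class WheelProjection:
    residues: str
    angles_deg: np.ndarray
    hydrophobicity: np.ndarray
    classes: list[str]          # per residue
    mu_H: float

    def residue_class(self, k: int) -> str:
        """Class of residue k (1-based)."""
        return self.classes[k - 1]


def _classify(residue: str) -> str:
    if residue in HYDROPHILIC_CHARGED:
        return "hydrophilic-charged"
    if residue in VERY_HYDROPHOBIC:
        return "very-hydrophobic"
    return "neutral/polar"


def hydrophobic_moment(peptide: str,
                       scale: dict[str, float] | None = None) -> float:
    """Length-normalized hydrophobic moment
    mu_H = | sum_k h_k exp(i theta_k) | / L with theta_k = (k-1)*100 deg."""
    peptide = _check_peptide(peptide)
    scale = scale or EISENBERG_CONSENSUS
    total = sum(
        scale[aa] * cmath.exp(1j * math.radians((k) * WHEEL_STEP_DEG))
        for k, aa in enumerate(peptide)
    )
    return abs(total) / len(peptide)


def helical_wheel(peptide: str,
                  scale: dict[str, float] | None = None) -> WheelProjection:
    """Schiffer-Edmundson projection with per-residue class and mu_H."""
    peptide = _check_peptide(peptide)
    if len(peptide) < 3:
        raise ValueError("peptide must have at least 3 residues")
    scale = scale or EISENBERG_CONSENSUS
    angles = (np.arange(len(peptide)) * WHEEL_STEP_DEG) % 360.0
    h = np.array([scale[aa] for aa in peptide])
    classes = [_classify(aa) for aa in peptide]
    return WheelProjection(peptide, angles, h, classes,
                           hydrophobic_moment(peptide, scale))


def amphipathicity_delta(peptide: str, position: int, replacement: str,
                         scale: dict[str, float] | None = None) -> float:
    """Change in mu_H when residue at ``position`` (1-based) is replaced:
    mu_H(modified) - mu_H(original)."""
    peptide = _check_peptide(peptide)
    replacement = _check_peptide(replacement)
    if len(replacement) != 1:
        raise ValueError("replacement must be a single residue")
    if not 1 <= position <= len(peptide):
        raise ValueError(
            f"position {position} outside peptide of length {len(peptide)}"
        )
    modified = peptide[:position - 1] + replacement + peptide[position:]
    return (hydrophobic_moment(modified, scale)
            - hydrophobic_moment(peptide, scale))
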