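"""Side-chain orientation of residue pairs.

For a pair (a, b), residue a's side chain *points toward* b when the
angle between the vector CA_a → side-chain-center_a and the vector
CA_a → CA_b is strictly less than π/2 — equivalently, when their dot
product is strictly positive.  Repeating the test from b's side yields
three pair classes: both side chains toward each other (type i), one
toward / one away (type ii), or both away (type iii), reflecting whether
the physical interaction is likely mediated by side-chain or backbone
atoms.

Glycine's side-chain center coincides with its CA, so its orientation
vector is zero and the angle is undefined; by default the zero dot
product fails the strict test ("not pointing toward"), keeping every
pair classifiable.  Summaries can instead exclude glycine-containing
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

from .contact_geometry import ReferenceMethod, reference_point
from .structure_io import ProteinStructure

__all__ = [
    "OrientationType",
    "OrientationSummary",
    "points_toward",
    "classify_pair",
    "orientation_summary",
]


class OrientationType(str, Enum):
    BOTH_TOWARD = "both_toward"  # type i
    MIXED = "mixed"              # type ii
    BOTH_AWAY = "both_away"      # type iii


@dataclass(frozen=True)
class OrientationSummary:
    fractions: dict
    n_pairs: int

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")


def _sc_vector(s: ProteinStructure, idx: int) -> np.ndarray:
    r = s.residues[idx - 1]
    ca = r.atom("CA").coords
    sc = reference_point(r, ReferenceMethod.SC_CENTER, allow_ca_fallback=s.sc_fallback)
    return sc - ca


def points_toward(s: ProteinStructure, a: int, b: int) -> bool:
    """True iff residue a's side chain points toward residue b."""
    if a == b:
        raise ValueError("a and b must differ")
    v_sc = _sc_vector(s, a)
    v_ab = s.residues[b - 1].atom("CA").coords - s.residues[a - 1].atom("CA").coords
    # strict < pi/2 test: boundary (dot == 0) and glycine's zero vector fail
    return float(np.dot(v_sc, v_ab)) > 0.0


def classify_pair(s: ProteinStructure, a: int, b: int) -> OrientationType:
    """Orientation class of a residue pair; symmetric in (a, b)."""
    ab = points_toward(s, a, b)
    ba = points_toward(s, b, a)
    if ab and ba:
        return OrientationType.BOTH_TOWARD
    if not ab and not ba:
        return OrientationType.BOTH_AWAY
    return OrientationType.MIXED


def orientation_summary(
    s: ProteinStructure,
    pairs: Iterable[tuple[int, int]],
    *,
    exclude_glycine: bool = False,
) -> OrientationSummary:
    """Orientation-class fractions over a set of residue pairs.

    Callers pass all eligible pairs, a contact map's pairs, or the
    top-k coupling pairs.  With ``exclude_glycine`` pairs containing a
    glycine are dropped before counting.
    """
    pairs = list(pairs)
    if exclude_glycine:
        pairs = [(i, j) for i, j in pairs
                 if s.residues[i - 1].aa != "G" and s.residues[j - 1].aa != "G"]
    if not pairs:
        raise ValueError("no pairs to classify")
    counts = {t: 0 for t in OrientationType}
    for i, j in pairs:
        counts[classify_pair(s, i, j)] += 1
    n = len(pairs)
    return OrientationSummary(
        fractions={t: counts[t] / n for t in OrientationType},
        n_pairs=n,
    )
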