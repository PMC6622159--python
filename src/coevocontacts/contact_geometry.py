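"""Residue-residue distance matrices and contact maps.

Five reference methods are supported for measuring the distance between
two residues:

``CA``
    distance between the alpha-carbon atoms;
``CB``
    distance between the beta-carbon atoms (glycine: CA);
``SC_CENTER``
    distance between side-chain geometric centers — the unweighted mean
    of each residue's non-backbone heavy-atom coordinates, CB included,
    CA excluded (glycine: CA);
``MIN_ALL``
    minimum distance over all heavy-atom pairs;
``MIN_SC``
    minimum distance over side-chain heavy-atom pairs (glycine
    contributes its CA).

Contacts are residue pairs at least ``min_sep`` apart along the chain
(default 12, i.e. ``j - i >= 12``) whose distance falls at or below a
cutoff.  Besides a fixed cutoff, a matched-count mode selects the n
closest eligible pairs so that different methods classify the same
number of contacts on a given structure and their accuracy can be
compared on an equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .structure_io import ProteinStructure, Residue, atom_subset

__all__ = [
    "ReferenceMethod",
    "DistanceMatrix",
    "ContactMap",
    "MatchedCutoffResult",
    "reference_point",
    "pair_distance",
    "distance_matrix",
    "contacts_fixed",
    "contacts_matched",
    "overlap_fraction",
    "distance_correlation",
    "eligible_pairs",
    "write_contacts",
    "write_casp_rr",
]

DEFAULT_MIN_SEP = 12


class ReferenceMethod(str, Enum):
    """How the distance between two residues is measured."""

    CA = "CA"
    CB = "CB"
    SC_CENTER = "SC_CENTER"
    MIN_ALL = "MIN_ALL"
    MIN_SC = "MIN_SC"


_POINT_METHODS = {ReferenceMethod.CA, ReferenceMethod.CB, ReferenceMethod.SC_CENTER}


@dataclass(frozen=True)
class DistanceMatrix:
    method: ReferenceMethod
    d: np.ndarray  # symmetric L x L, Å

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "d", d)

    @property
    def L(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class ContactMap:
    method: ReferenceMethod
    L: int
    min_sep: int
    cutoff: float
    pairs: frozenset[tuple[int, int]]  # 1-based, i < j

    def __post_init__(self):
        for i, j in self.pairs:
            if not (1 <= i < j <= self.L) or j - i < self.min_sep:
                raise ValueError(f"pair ({i}, {j}) violates ordering or min_sep")


@dataclass(frozen=True)
class MatchedCutoffResult:
    contact_map: ContactMap
    effective_cutoff: float
    n: int


def reference_point(residue: Residue, method: ReferenceMethod, *, allow_ca_fallback: bool = False) -> np.ndarray:
    """Reference coordinate of a residue under a point-based method."""
    method = ReferenceMethod(method)
    if method not in _POINT_METHODS:
        raise ValueError(f"{method.value} has no single reference point")
    ca = residue.atom("CA")
    if method is ReferenceMethod.CA or residue.aa == "G":
        return ca.coords
    if method is ReferenceMethod.CB:
        cb = residue.atom("CB")
        if cb is None:
            if allow_ca_fallback:
                return ca.coords
            raise ValueError(f"residue {residue.index} ({residue.aa}): no CB atom")
        return cb.coords
    sc = atom_subset(residue, "side_chain", allow_ca_fallback=allow_ca_fallback)
    return np.mean([a.coords for a in sc], axis=0)


def _atom_coords(residue: Residue, method: ReferenceMethod, allow_ca_fallback: bool) -> np.ndarray:
    subset = "all_heavy" if method is ReferenceMethod.MIN_ALL else "side_chain"
    atoms = atom_subset(residue, subset, allow_ca_fallback=allow_ca_fallback)
    return np.array([a.coords for a in atoms])


def pair_distance(a: Residue, b: Residue, method: ReferenceMethod, *, allow_ca_fallback: bool = False) -> float:
    """Euclidean distance between two residues under one method, in Å."""
    method = ReferenceMethod(method)
    if method in _POINT_METHODS:
        pa = reference_point(a, method, allow_ca_fallback=allow_ca_fallback)
        pb = reference_point(b, method, allow_ca_fallback=allow_ca_fallback)
        return float(np.linalg.norm(pa - pb))
    return float(cdist(_atom_coords(a, method, allow_ca_fallback),
                       _atom_coords(b, method, allow_ca_fallback)).min())


def distance_matrix(s: ProteinStructure, method: ReferenceMethod) -> DistanceMatrix:
    """All pairwise residue distances of a cleaned structure."""
    method = ReferenceMethod(method)
    fallback = s.sc_fallback
    if method in _POINT_METHODS:
        pts = np.array([reference_point(r, method, allow_ca_fallback=fallback)
                        for r in s.residues])
        d = cdist(pts, pts)
    else:
        coords = []
        starts = []
        for r in s.residues:
            starts.append(len(coords))
            coords.extend(_atom_coords(r, method, fallback))
        A = np.asarray(coords)
        # min-reduce the atom-level distance matrix into residue blocks
        dd = cdist(A, A)
        dd = np.minimum.reduceat(dd, starts, axis=0)
        d = np.minimum.reduceat(dd, starts, axis=1)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(method=method, d=d)


def eligible_pairs(L: int, min_sep: int = DEFAULT_MIN_SEP) -> list[tuple[int, int]]:
    """All 1-based pairs (i, j) with j - i >= min_sep, lexicographic order."""
    return [(i, j) for i in range(1, L + 1) for j in range(i + min_sep, L + 1)]


def _eligible_index(L: int, min_sep: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(L, k=min_sep)
    return iu[0] + 1, iu[1] + 1


def contacts_fixed(dm: DistanceMatrix, cutoff: float, min_sep: int = DEFAULT_MIN_SEP) -> ContactMap:
    """Contacts at a fixed distance cutoff (inclusive boundary)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    ii, jj = _eligible_index(dm.L, min_sep)
    dist = dm.d[ii - 1, jj - 1]
    keep = dist <= cutoff
    pairs = frozenset(zip(ii[keep].tolist(), jj[keep].tolist()))
    return ContactMap(method=dm.method, L=dm.L, min_sep=min_sep, cutoff=float(cutoff), pairs=pairs)


def contacts_matched(dm: DistanceMatrix, n: int, min_sep: int = DEFAULT_MIN_SEP) -> MatchedCutoffResult:
    """The n closest eligible pairs; ties broken by (distance, i, j)."""
    ii, jj = _eligible_index(dm.L, min_sep)
    if n > ii.size:
        raise ValueError(f"n={n} exceeds the {ii.size} eligible pairs")
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = dm.d[ii - 1, jj - 1]
    order = np.lexsort((jj, ii, dist))[:n]
    pairs = frozenset(zip(ii[order].tolist(), jj[order].tolist()))
    effective = float(np.sort(dist)[n - 1])
    cm = ContactMap(method=dm.method, L=dm.L, min_sep=min_sep, cutoff=effective, pairs=pairs)
    return MatchedCutoffResult(contact_map=cm, effective_cutoff=effective, n=n)


def overlap_fraction(a: ContactMap, b: ContactMap) -> float:
    """Fraction of count-matched contacts shared by two maps."""
    if a.L != b.L or a.min_sep != b.min_sep:
        raise ValueError("contact maps must share L and min_sep")
    if len(a.pairs) != len(b.pairs):
        raise ValueError(
            f"overlap is defined for count-matched maps ({len(a.pairs)} vs {len(b.pairs)} contacts)"
        )
    if not a.pairs:
        raise ValueError("empty contact maps")
    return len(a.pairs & b.pairs) / len(a.pairs)


def distance_correlation(a: DistanceMatrix, b: DistanceMatrix, min_sep: int = DEFAULT_MIN_SEP) -> float:
    """Spearman rank correlation of eligible-pair distances."""
    if a.L != b.L:
        raise ValueError("distance matrices must share L")
    ii, jj = _eligible_index(a.L, min_sep)
    if ii.size < 3:
        raise ValueError("fewer than 3 eligible pairs")
    rho = spearmanr(a.d[ii - 1, jj - 1], b.d[ii - 1, jj - 1]).statistic
    return float(rho)


def write_contacts(cm: ContactMap, dm: DistanceMatrix, path: str | Path) -> None:
    """Write contacts as 'i j distance method' lines, 1-based, i < j."""
    lines = [
        f"{i} {j} {dm.d[i - 1, j - 1]:.4f} {cm.method.value}"
        for i, j in sorted(cm.pairs)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_casp_rr(cm: ContactMap, path: str | Path, confidence: float = 1.0) -> None:
    """Write contacts in CASP-RR style: 'i j 0 cutoff confidence'."""
    lines = [
        f"{i} {j} 0 {cm.cutoff:.2f} {confidence:.3f}"
        for i, j in sorted(cm.pairs)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
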