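"""Coupling-score matrices: an MI+APC scorer and readers for external
matrices.

The scorer measures direct covariation between alignment columns as
mutual information over a 21-state alphabet (20 amino acids + gap),

    MI_ij = sum_ab f_ij(a,b) ln[ f_ij(a,b) / (f_i(a) f_j(b)) ],

with sequences optionally down-weighted by local redundancy (a sequence
with many near-duplicates at >= 80% identity counts less) and
frequencies smoothed by a small pseudocount.  The average product
correction (APC) removes the column-wise background that inflates MI at
conserved or gappy positions:

    S_ij = MI_ij - (M_i * M_j) / M_bar,

where M_i is the mean MI of column i against all other columns and
M_bar the grand mean.  This is deliberately a transparent
frequency-based scorer, not a pseudolikelihood or inverse-covariance
method; it shares the interface of the matrix readers, which ingest
scores produced by any external coupling program (plain L x L text, or
1-based "i j score" edge lists).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_io import GAP, Alignment

__all__ = [
    "CouplingMatrix",
    "RankedPairs",
    "sequence_weights",
    "mi_matrix",
    "apply_apc",
    "mi_apc",
    "planted_pair_mi",
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "rank_pairs",
]

N_STATES = 21


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric L x L coupling scores; the diagonal is ignored."""

    s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("coupling matrix must be square")
        off = ~np.eye(s.shape[0], dtype=bool)
        if not np.all(np.isfinite(s[off])):
            raise ValueError("off-diagonal scores must be finite")
        if not np.allclose(s[off], s.T[off]):
            raise ValueError("coupling matrix must be symmetric")
        object.__setattr__(self, "s", s)

    @property
    def L(self) -> int:
        return self.s.shape[0]


@dataclass(frozen=True)
class RankedPairs:
    """Eligible pairs ordered by score descending, ties by (i, j)."""

    pairs: tuple[tuple[int, int, float], ...]  # (i, j, score), 1-based, i < j
    L: int
    min_sep: int

    def top(self, k: int) -> list[tuple[int, int]]:
        if k > len(self.pairs):
            raise ValueError(f"k={k} exceeds the {len(self.pairs)} eligible pairs")
        return [(i, j) for i, j, _ in self.pairs[:k]]

    def __len__(self) -> int:
        return len(self.pairs)


def sequence_weights(aln: Alignment, identity_threshold: float = 0.8) -> np.ndarray:
    """Redundancy weights: 1 / #(sequences at >= threshold identity, self included).

    Fractional identity is the fraction of alignment columns at which two
    rows carry the same state (gaps compare as a state).
    """
    X = aln.matrix
    n, L = X.shape
    # one-hot trick: the dot product of one-hot rows counts matching columns
    onehot = np.zeros((n, L * N_STATES), dtype=np.float32)
    cols = np.arange(L) * N_STATES
    onehot[np.arange(n)[:, None], cols + X] = 1.0
    matches = onehot @ onehot.T
    neighbors = (matches >= identity_threshold * L - 1e-9).sum(axis=1)
    return 1.0 / neighbors.astype(float)


def _frequencies(aln: Alignment, pseudocount: float, weights: np.ndarray | None):
    X = aln.matrix
    n, L = X.shape
    if n < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must have one entry per sequence")
    neff = w.sum()

    onehot = np.zeros((n, L * N_STATES), dtype=np.float32)
    cols = np.arange(L) * N_STATES
    onehot[np.arange(n)[:, None], cols + X] = 1.0
    # weighted joint counts for every column pair in one rank-deficient GEMM
    C = (onehot * w[:, None].astype(np.float32)).T @ onehot
    C = C.reshape(L, N_STATES, L, N_STATES).transpose(0, 2, 1, 3).astype(float)

    # lambda per state on single sites, lambda/q per joint cell: the pair
    # marginals then reduce exactly to the single-site frequencies
    denom = neff + N_STATES * pseudocount
    fij = (C + pseudocount / N_STATES) / denom
    ci = (onehot * w[:, None].astype(np.float32)).sum(axis=0).reshape(L, N_STATES).astype(float)
    fi = (ci + pseudocount) / denom
    return fi, fij


def mi_matrix(
    aln: Alignment,
    pseudocount: float = 0.5,
    weights: np.ndarray | None = None,
) -> CouplingMatrix:
    """Raw (uncorrected) mutual information between all column pairs, in nats."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    fi, fij = _frequencies(aln, pseudocount, weights)
    # MI from the smoothed joint and its own marginals (guarantees MI >= 0)
    mi = np.einsum("ijab,ijab->ij", fij, np.log(fij))
    mi -= np.einsum("ijab,ia->ij", fij, np.log(fi))
    mi -= np.einsum("ijab,jb->ij", fij, np.log(fi))
    np.fill_diagonal(mi, 0.0)
    mi = (mi + mi.T) / 2
    return CouplingMatrix(s=mi)


def apply_apc(cm: CouplingMatrix) -> CouplingMatrix:
    """Average product correction: S_ij = MI_ij - M_i M_j / M_bar."""
    m = cm.s.copy()
    L = cm.L
    off = ~np.eye(L, dtype=bool)
    col_mean = m.sum(axis=1) / (L - 1)
    grand = m[off].mean()
    if grand == 0:
        return CouplingMatrix(s=m)
    corrected = m - np.outer(col_mean, col_mean) / grand
    np.fill_diagonal(corrected, 0.0)
    return CouplingMatrix(s=corrected)


def mi_apc(
    aln: Alignment,
    pseudocount: float = 0.5,
    weights: np.ndarray | None = None,
) -> CouplingMatrix:
    """APC-corrected mutual-information coupling scores."""
    return apply_apc(mi_matrix(aln, pseudocount, weights))


def planted_pair_mi(c: float, q: int = 20) -> float:
    """Closed-form MI (nats) of one planted pair at correlation strength c.

    Under the planted model the joint distribution of a pair is a mixture:
    with probability c the second state is a fixed bijection of the first,
    otherwise the two are independent and uniform over q states.
    """
    if not 0 <= c <= 1:
        raise ValueError("c must be in [0, 1]")
    on = c + (1 - c) / q
    out = on * np.log(c * q + 1 - c)
    if c < 1:
        out += (1 - c) * (1 - 1 / q) * np.log(1 - c)
    return float(out)


def read_matrix(source: str | Path) -> CouplingMatrix:
    """Read a plain-text L x L score matrix (CCMpred output dialect).

    Asymmetric input is symmetrised by the elementwise maximum.
    """
    text_mode = isinstance(source, str) and "\n" in source
    s = np.loadtxt(Path(source).open() if not text_mode else source.splitlines())
    s = np.atleast_2d(s)
    if s.shape[0] != s.shape[1]:
        raise ValueError(f"matrix is {s.shape[0]}x{s.shape[1]}, not square")
    s = np.maximum(s, s.T)
    np.fill_diagonal(s, 0.0)
    return CouplingMatrix(s=s)


def write_matrix(cm: CouplingMatrix, path: str | Path) -> None:
    np.savetxt(path, cm.s, fmt="%.8g")


def read_edge_list(source: str | Path, L: int) -> CouplingMatrix:
    """Read 1-based 'i j score' lines (plmc-style) into an L x L matrix."""
    text_mode = isinstance(source, str) and "\n" in source
    text = source if text_mode else Path(source).read_text()
    s = np.zeros((L, L))
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split()
        i, j, score = int(parts[0]), int(parts[1]), float(parts[2])
        if not (1 <= i <= L and 1 <= j <= L):
            raise ValueError(f"edge ({i}, {j}) outside 1..{L}")
        s[i - 1, j - 1] = s[j - 1, i - 1] = score
    return CouplingMatrix(s=s)


def rank_pairs(cm: CouplingMatrix, min_sep: int = 12) -> RankedPairs:
    """Eligible pairs sorted by score descending; ties broken by (i, j)."""
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    L = cm.L
    iu = np.triu_indices(L, k=min_sep)
    scores = cm.s[iu]
    order = np.lexsort((iu[1], iu[0], -scores))
    pairs = tuple(
        (int(iu[0][k]) + 1, int(iu[1][k]) + 1, float(scores[k])) for k in order
    )
    return RankedPairs(pairs=pairs, L=L, min_sep=min_sep)
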