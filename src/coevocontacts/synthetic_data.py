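"""Synthetic structures and alignments with planted covariation.

Two generators make every stage of the analysis testable without any
external data:

* :func:`synth_structure` builds a compact, self-avoiding CA trace with
  3.8 Å consecutive spacing, minimal backbone atoms and 1-3 pseudo
  side-chain atoms per residue extending along a per-residue direction
  drawn isotropically.  The result is a regular cleaned structure, so
  all five contact definitions apply to it, and because side chains
  point in random directions its CA- and side-chain-center-defined
  contact maps genuinely disagree, as they do for real proteins.

* :func:`synth_alignment` plants pairwise covariation at a structure's
  contacts.  Sites are paired one-to-one by a maximum-cardinality
  matching on the contact graph (each site in at most one pair, as many
  contacts as possible carrying signal); within a pair, with probability
  ``c`` the second state is a fixed random bijection of the first,
  otherwise both are independent and uniform over ``q`` amino acids.  Sequences are
  i.i.d. — there is no phylogeny — so the mutual information of a
  planted pair has the closed form
  ``MI(c) = (c + (1-c)/q) ln(cq + 1-c) + (1-c)(1-1/q) ln(1-c)``,
  an analytic oracle for the coupling scorer.

The generator's coupling strength ``c`` plays the role that selection
strength plays in stability-constrained evolutionary simulations: it
dials how deterministically a substitution at one site of a contact is
compensated at the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Alignment
from .contact_geometry import (
    ReferenceMethod,
    contacts_fixed,
    contacts_matched,
    distance_matrix,
)
from .structure_io import Atom, ProteinStructure, Residue

__all__ = ["SynthParams", "synth_structure", "planted_pairs", "synth_alignment"]

#: amino acids ordered as in the alignment alphabet; glycine is "G"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CA_STEP = 3.8      # Å between consecutive CA atoms
_CLASH = 4.0        # Å minimum CA-CA distance for non-consecutive residues


@dataclass(frozen=True)
class SynthParams:
    """Conditions for the synthetic structure/alignment generators."""

    L: int = 100                 # chain length
    N: int = 3000                # number of sequences
    c: float = 0.7               # pair correlation strength in [0, 1]
    q: int = 20                  # alphabet size for sequence sampling
    planted_on: ReferenceMethod = ReferenceMethod.SC_CENTER
    seed: int = 0
    compactness: float | None = None   # target radius of gyration, Å
    sc_length_range: tuple[float, float] = (1.5, 4.0)
    gly_fraction: float = 0.05   # expected fraction of glycines
    #: weight of the packing term in side-chain directions: 0 (default)
    #: gives isotropic side chains; positive values tilt each side chain
    #: toward the mean of the spatially close, sequence-distant residues
    #: around it, mimicking buried side-chain packing
    packing_bias: float = 0.0
    min_sep: int = 12
    ca_cutoff: float = 8.0       # defines the matched contact count

    def __post_init__(self):
        if not 0 <= self.c <= 1:
            raise ValueError("c must be in [0, 1]")
        if self.L < 30:
            raise ValueError("L must be >= 30 so pairs at min_sep >= 12 exist")
        if self.N < 2:
            raise ValueError("N must be >= 2")

    @property
    def target_rg(self) -> float:
        if self.compactness is not None:
            return self.compactness
        # dense-globule scaling: ~90 Å^3 of confining sphere per residue
        # (tighter than an all-atom protein because the pseudo side
        # chains carry only 1-3 atoms); gives 2-3 long-range contacts
        # per residue, the density of a globular domain
        radius = (3.0 * self.L * 90.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        return radius * np.sqrt(3.0 / 5.0)


def _isotropic(rng: np.random.Generator, size=None) -> np.ndarray:
    v = rng.normal(size=(size, 3) if size else 3)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _ca_trace(p: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding walk confined to a sphere.

    Confinement to a sphere of radius ``target_rg / sqrt(3/5)`` makes the
    chain fold back on itself repeatedly, giving the long-range contact
    density of a globular domain.  A stuck step backtracks before the
    whole chain is restarted.
    """
    R = p.target_rg / np.sqrt(3.0 / 5.0)  # sphere radius for uniform density
    for _restart in range(200):
        start = _isotropic(rng) * rng.uniform(0, R * 0.5)
        pts = [start]
        backtracks = 0
        while len(pts) < p.L:
            placed = False
            for _try in range(150):
                cand = pts[-1] + _CA_STEP * _isotropic(rng)
                if np.linalg.norm(cand) > R:
                    continue
                if len(pts) >= 2 and np.min(
                    np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                ) < _CLASH:
                    continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                if len(pts) > 2 and backtracks < 100:
                    pts.pop()
                    backtracks += 1
                else:
                    break
        if len(pts) == p.L:
            return np.asarray(pts)
    raise RuntimeError(f"failed to build a self-avoiding trace (seed={p.seed})")


def synth_structure(p: SynthParams) -> ProteinStructure:
    """Generate a toy cleaned structure; deterministic for a given seed."""
    rng = np.random.default_rng(p.seed)
    ca = _ca_trace(p, rng)

    n_gly = int(round(p.gly_fraction * p.L))
    gly_sites = set(rng.choice(p.L, size=n_gly, replace=False).tolist()) if n_gly else set()
    other = [a for a in _AA20 if a != "G"]

    # packing environment: mean direction toward spatially close (<= 10 Å)
    # but sequence-distant (>= 6 apart) residues, if any
    D = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    sep = np.abs(np.subtract.outer(np.arange(p.L), np.arange(p.L)))
    neigh_mask = (D <= 10.0) & (sep >= 6)

    lo, hi = p.sc_length_range
    sc_names = ["CG", "CD", "CE"]
    residues = []
    for k in range(p.L):
        aa = "G" if k in gly_sites else other[rng.integers(len(other))]
        atoms = [Atom("CA", "C", ca[k])]
        # minimal backbone: N toward the previous CA, C toward the next, O off C
        if k > 0:
            u = ca[k - 1] - ca[k]
            atoms.append(Atom("N", "N", ca[k] + 1.2 * u / np.linalg.norm(u)))
        if k < p.L - 1:
            u = ca[k + 1] - ca[k]
            cpos = ca[k] + 1.2 * u / np.linalg.norm(u)
            atoms.append(Atom("C", "C", cpos))
            atoms.append(Atom("O", "O", cpos + 1.23 * _isotropic(rng)))
        if aa != "G":
            u = _isotropic(rng)
            if p.packing_bias > 0 and neigh_mask[k].any():
                t = ca[neigh_mask[k]].mean(axis=0) - ca[k]
                nt = np.linalg.norm(t)
                if nt > 1e-9:
                    u = 0.7 * u + p.packing_bias * t / nt
                    u /= np.linalg.norm(u)
            atoms.append(Atom("CB", "C", ca[k] + 1.5 * u))
            n_extra = int(rng.integers(1, 4))
            d_max = rng.uniform(max(lo, 1.6), hi)
            for m in range(n_extra):
                d = 1.5 + (d_max - 1.5) * (m + 1) / n_extra
                jitter = 0.3 * _isotropic(rng)
                atoms.append(Atom(sc_names[m], "C", ca[k] + d * u + jitter))
        residues.append(Residue(k + 1, aa, tuple(atoms)))
    return ProteinStructure(chain_id="A", residues=tuple(residues))


def planted_pairs(structure: ProteinStructure, p: SynthParams) -> list[tuple[int, int]]:
    """Contacts selected for covariation planting, one pair per site.

    The pair pool is the matched-count contact map of the structure
    under ``p.planted_on`` (count matched to the CA contacts at
    ``p.ca_cutoff``).  Sites are paired by a maximum-cardinality
    matching on that contact graph, so as many contacts as possible
    carry covariation while every site belongs to at most one planted
    pair and the planted joint distribution stays exactly pairwise.
    The matching is indifferent to distance within the map, so planted
    pairs sample the whole contact map, not just its shortest edges.
    """
    import networkx as nx

    dm_ca = distance_matrix(structure, ReferenceMethod.CA)
    n = len(contacts_fixed(dm_ca, p.ca_cutoff, p.min_sep).pairs)
    if n == 0:
        raise ValueError("structure has no eligible contacts to plant on")
    dm = distance_matrix(structure, p.planted_on)
    cm = contacts_matched(dm, n, p.min_sep).contact_map
    G = nx.Graph()
    G.add_edges_from(sorted(cm.pairs))
    matching = nx.max_weight_matching(G, maxcardinality=True)
    return sorted((min(i, j), max(i, j)) for i, j in matching)


def synth_alignment(structure: ProteinStructure, p: SynthParams) -> Alignment:
    """Sample an i.i.d. alignment with covariation planted at contacts.

    Row 0 is the designated reference; there are no gaps.  Uses a seed
    derived from ``p.seed`` so structure and alignment randomness are
    independent streams.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
    pairs = planted_pairs(structure, p)
    X = rng.integers(0, p.q, size=(p.N, structure.L), dtype=np.uint8)
    for i, j in pairs:
        bijection = rng.permutation(p.q).astype(np.uint8)
        copy = rng.random(p.N) < p.c
        X[copy, j - 1] = bijection[X[copy, i - 1]]
    ids = tuple(f"seq{k}" for k in range(p.N))
    return Alignment(ids=ids, matrix=X, ref_row=0)
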