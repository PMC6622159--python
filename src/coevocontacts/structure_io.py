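"""Reading, cleaning and writing single-chain protein structures.

A cleaned structure keeps only the heavy atoms of standard amino-acid
residues from one chain of one model, renumbered consecutively 1..L.
Waters, other heteroatoms, hydrogens and all but one alternate location
per atom are discarded, so that downstream geometry (distance matrices,
side-chain centers, orientation vectors) is unambiguous.

Atom-subset conventions follow standard practice in contact-map work:
the backbone is N, CA, C, O (and the terminal OXT); everything else,
CB included, belongs to the side chain.  Glycine has no side-chain heavy
atom, so its CA doubles as the side-chain representative — the one
documented exception to the backbone/side-chain partition.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "load_structure",
    "atom_subset",
    "write_pdb",
    "MissingSideChainError",
    "NonStandardResidueError",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: non-standard residues optionally mapped onto a standard parent
NONSTANDARD_MAP = {"MSE": "MET", "SEC": "CYS"}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATERS = {"HOH", "WAT", "DOD"}


class NonStandardResidueError(ValueError):
    """A polymer residue is not one of the 20 standard amino acids."""


class MissingSideChainError(ValueError):
    """A non-glycine residue has no side-chain heavy atoms."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom with PDB-convention name and coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if self.element.upper() in ("H", "D"):
            raise ValueError(f"atom {self.name}: hydrogens are not retained")


@dataclass(frozen=True)
class Residue:
    """A cleaned residue: 1-based chain index, one-letter code, heavy atoms."""

    index: int
    aa: str
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if self.aa not in ONE_TO_THREE:
            raise NonStandardResidueError(f"residue {self.index}: unknown code {self.aa!r}")
        if self.atom("CA") is None:
            raise ValueError(f"residue {self.index} ({self.aa}): no CA atom")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class ProteinStructure:
    """An ordered, consecutively numbered single chain."""

    chain_id: str
    residues: tuple[Residue, ...]
    #: True when residues missing their side chain were accepted at load
    #: time and downstream geometry may fall back to CA for them.
    sc_fallback: bool = field(default=False)

    def __post_init__(self):
        for k, r in enumerate(self.residues, start=1):
            if r.index != k:
                raise ValueError(f"residue indices not consecutive at position {k}")

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


def atom_subset(
    residue: Residue,
    which: Literal["all_heavy", "backbone", "side_chain"],
    *,
    allow_ca_fallback: bool = False,
) -> list[Atom]:
    """Return the named heavy-atom subset of a residue.

    ``side_chain`` is every heavy atom not named N/CA/C/O/OXT (so CB is a
    side-chain atom); for glycine it is ``[CA]`` by convention.  A
    non-glycine residue with an empty side chain raises
    :class:`MissingSideChainError` unless ``allow_ca_fallback`` is set, in
    which case ``[CA]`` is returned with a warning.
    """
    if which == "all_heavy":
        return list(residue.atoms)
    if which == "backbone":
        return [a for a in residue.atoms if a.name in BACKBONE_ATOMS]
    if which != "side_chain":
        raise ValueError(f"unknown subset {which!r}")
    if residue.aa == "G":
        return [residue.atom("CA")]
    sc = [a for a in residue.atoms if a.name not in BACKBONE_ATOMS]
    if not sc:
        if allow_ca_fallback:
            warnings.warn(
                f"residue {residue.index} ({residue.aa}) has no side-chain atoms; "
                "using CA as fallback",
                stacklevel=2,
            )
            return [residue.atom("CA")]
        raise MissingSideChainError(
            f"residue {residue.index} ({residue.aa}) has no side-chain heavy atoms"
        )
    return sc


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def _is_polymer_chain(chain: gemmi.Chain) -> bool:
    names = {r.name for r in chain}
    return bool(names & (set(THREE_TO_ONE) | set(NONSTANDARD_MAP)))


def load_structure(
    pdb_source: str | Path,
    chain: str | None = None,
    *,
    map_nonstandard: bool = False,
    missing_side_chain: Literal["error", "ca"] = "error",
) -> ProteinStructure:
    """Load and clean one chain of a PDB entry.

    Parameters
    ----------
    pdb_source
        Path to a PDB file, or PDB-format text.
    chain
        Chain identifier; defaults to the first chain containing
        amino-acid residues.
    map_nonstandard
        Map MSE→MET and SEC→CYS instead of raising on them.
    missing_side_chain
        Policy for non-glycine residues missing every side-chain heavy
        atom: ``"error"`` (default) raises at load time, ``"ca"`` accepts
        them and lets geometry fall back to the CA coordinate.

    Cleaning drops HETATM records (waters, ligands), hydrogens/deuteriums
    and all but the most occupied alternate location of each atom; the
    first model is used and residues are renumbered 1..L.
    """
    text_mode = isinstance(pdb_source, str) and "\n" in pdb_source
    if text_mode:
        st = gemmi.read_pdb_string(pdb_source)
    else:
        st = gemmi.read_pdb(str(pdb_source))
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]

    gchain = None
    if chain is not None:
        for c in model:
            if c.name == chain:
                gchain = c
                break
        if gchain is None:
            raise ValueError(f"chain {chain!r} not found")
    else:
        for c in model:
            if _is_polymer_chain(c):
                gchain = c
                break
        if gchain is None:
            raise ValueError("no amino-acid chain found")

    residues: list[Residue] = []
    for gres in gchain:
        name = gres.name.upper()
        if name in _WATERS:
            continue
        if name in NONSTANDARD_MAP:
            if map_nonstandard:
                name = NONSTANDARD_MAP[name]
            else:
                raise NonStandardResidueError(
                    f"non-standard residue {gres.name} at {gres.seqid}; "
                    "set map_nonstandard=True to map MSE/SEC"
                )
        if name not in THREE_TO_ONE:
            if gres.het_flag == "H":
                continue  # ligand / modified hetero group: dropped
            raise NonStandardResidueError(
                f"unknown residue {gres.name} at {gres.seqid}"
            )
        by_name: dict[str, list[gemmi.Atom]] = {}
        for ga in gres:
            if ga.element.is_hydrogen:
                continue
            by_name.setdefault(ga.name, []).append(ga)
        atoms = []
        for aname in by_name:
            ga = _pick_altloc(by_name[aname])
            el = ga.element.name if ga.element.name else aname[0]
            atoms.append(Atom(aname, el, np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
        if not atoms:
            continue
        residues.append(Residue(len(residues) + 1, THREE_TO_ONE[name], tuple(atoms)))

    if not residues:
        raise ValueError(f"chain {gchain.name!r} contains no amino-acid residues")

    struct = ProteinStructure(
        chain_id=gchain.name,
        residues=tuple(residues),
        sc_fallback=(missing_side_chain == "ca"),
    )
    if missing_side_chain == "error":
        for r in struct.residues:
            atom_subset(r, "side_chain")  # raises MissingSideChainError if empty
    return struct


def write_pdb(s: ProteinStructure, path: str | Path | None = None) -> str:
    """Write the cleaned structure as standard PDB ATOM records.

    Returns the PDB text; also writes it to ``path`` when given.  The
    round trip through :func:`load_structure` preserves coordinates to
    the PDB format's 1e-3 Å precision.
    """
    st = gemmi.Structure()
    st.name = "cleaned"
    model = gemmi.Model("1")
    ch = gemmi.Chain(s.chain_id or "A")
    for r in s.residues:
        gres = gemmi.Residue()
        gres.name = ONE_TO_THREE[r.aa]
        gres.seqid = gemmi.SeqId(r.index, " ")
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = 1.0
            gres.add_atom(ga)
        ch.add_residue(gres)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
    if path is not None:
        Path(path).write_text(text)
    return text
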