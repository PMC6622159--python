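"""Shared fixtures: hand-written PDB snippets and cached synthetic data."""

import numpy as np
import pytest

from coevocontacts.structure_io import Atom, ProteinStructure, Residue
from coevocontacts.synthetic_data import SynthParams, synth_alignment, synth_structure


def pdb_line(serial, name, resname, resseq, x, y, z, element, altloc=" ", occ=1.0, record="ATOM"):
    padded = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {padded}{altloc}{resname:<3} A{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}"
    )


_pdb_line = pdb_line


@pytest.fixture
def two_residue_pdb() -> str:
    """Minimal GLY-ALA chain with full heavy atoms."""
    lines = [
        _pdb_line(1, "N", "GLY", 1, 0.0, 1.4, 0.0, "N"),
        _pdb_line(2, "CA", "GLY", 1, 0.0, 0.0, 0.0, "C"),
        _pdb_line(3, "C", "GLY", 1, 1.4, -0.6, 0.0, "C"),
        _pdb_line(4, "O", "GLY", 1, 1.5, -1.8, 0.0, "O"),
        _pdb_line(5, "N", "ALA", 2, 2.4, 0.2, 0.0, "N"),
        _pdb_line(6, "CA", "ALA", 2, 3.8, 0.0, 0.0, "C"),
        _pdb_line(7, "C", "ALA", 2, 4.5, 1.3, 0.0, "C"),
        _pdb_line(8, "O", "ALA", 2, 5.7, 1.4, 0.0, "O"),
        _pdb_line(9, "CB", "ALA", 2, 4.3, -0.8, 1.2, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_residue_pdb_with_water(two_residue_pdb) -> str:
    water = _pdb_line(10, "O", "HOH", 99, 9.0, 9.0, 9.0, "O", record="HETATM")
    return two_residue_pdb.replace("END", water + "\nEND")


def make_residue(index, aa, named_coords):
    """Residue from {atom name: xyz}; element inferred from the name."""
    atoms = tuple(
        Atom(name, name[0], np.asarray(xyz, dtype=float))
        for name, xyz in named_coords.items()
    )
    return Residue(index, aa, atoms)


def make_chain(residue_specs):
    """Structure from a list of (aa, {atom: xyz}) specs, numbered 1..L."""
    residues = tuple(
        make_residue(k + 1, aa, coords) for k, (aa, coords) in enumerate(residue_specs)
    )
    return ProteinStructure(chain_id="A", residues=residues)


def random_structure(rng, L=8, n_sc=2, spread=10.0):
    """Small random structure with CA/CB plus extra side-chain atoms."""
    specs = []
    for _ in range(L):
        base = rng.uniform(-spread, spread, 3)
        coords = {"CA": base, "N": base + rng.normal(0, 0.5, 3), "C": base + rng.normal(0, 0.5, 3)}
        coords["CB"] = base + rng.normal(0, 1.0, 3)
        for m in range(rng.integers(0, n_sc + 1)):
            coords[["CG", "CD"][m]] = base + rng.normal(0, 1.5, 3)
        specs.append(("A", coords))
    return make_chain(specs)


@pytest.fixture(scope="session")
def small_synth():
    """One modest planted dataset reused across tests (L=60, N=400)."""
    p = SynthParams(L=60, N=400, c=0.9, seed=7)
    s = synth_structure(p)
    return p, s, synth_alignment(s, p)


@pytest.fixture(scope="session")
def planted_setup():
    """The default study conditions (L=100, N=3000, c=0.7), one seed."""
    p = SynthParams(seed=0)
    s = synth_structure(p)
    return p, s, synth_alignment(s, p)
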