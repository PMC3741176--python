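"""Shared fixtures: handcrafted PDB text and geometric SASA fixtures."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from psychrotryp.structure import Atom, Structure


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    altloc: str = " ",
    record: str = "ATOM",
) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}{resseq:>4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def icosahedron_vertices() -> np.ndarray:
    phi = (1 + 5**0.5) / 2
    verts = []
    for a, b in itertools.product((-1.0, 1.0), repeat=2):
        verts += [(0.0, a, b * phi), (a, b * phi, 0.0), (a * phi, 0.0, b)]
    v = np.array(verts)
    return v / np.linalg.norm(v, axis=1)[:, None]


@pytest.fixture
def cage_structure() -> Structure:
    """A carbon atom enclosed by 12 overlapping icosahedral neighbors."""
    atoms = [Atom(1, "C1", "UNK", "A", 1, 0.0, 0.0, 0.0, "C")]
    for i, v in enumerate(icosahedron_vertices() * 3.0):
        atoms.append(Atom(i + 2, "C1", "UNK", "A", i + 2, v[0], v[1], v[2], "C"))
    return Structure(atoms=atoms)


@pytest.fixture
def cage_residue_structure() -> Structure:
    """An alanine whose CB sits at the center of the 12-neighbor cage."""
    atoms = [
        Atom(1, "N", "ALA", "A", 1, 0.0, 1.46, 0.0, "N"),
        Atom(2, "CA", "ALA", "A", 1, 0.9, 0.7, 0.0, "C"),
        Atom(3, "C", "ALA", "A", 1, 2.0, 1.2, 0.8, "C"),
        Atom(4, "O", "ALA", "A", 1, 2.1, 2.4, 0.9, "O"),
        Atom(5, "CB", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
    ]
    for i, v in enumerate(icosahedron_vertices() * 3.0):
        atoms.append(Atom(i + 6, "C1", "UNK", "A", i + 2, v[0], v[1], v[2], "C"))
    return Structure(atoms=atoms)
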