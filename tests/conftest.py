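"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by the most literal means
available (triple loops over every grid cell, per-point pairwise binning) so
that the vectorised implementations are checked against something that
cannot share their bugs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from molcarto import ToySpec, parse_pdb
from molcarto.fixtures import make_toy_structure
from molcarto.pdb_io import Structure

RESIDUES = ["ALA", "ARG", "ASP", "GLY", "LEU", "TRP"]


def structure_from_atoms(atoms: list[tuple[str, tuple[float, float, float]]]) -> Structure:
    """Build a Structure by writing and re-parsing minimal PDB text."""
    return parse_pdb(make_toy_structure(ToySpec(atoms=atoms)), source_id="toy")


def random_structure(rng: np.random.Generator, max_atoms: int = 30,
                     extent: float = 12.0) -> Structure:
    n = int(rng.integers(1, max_atoms + 1))
    atoms = [
        (
            RESIDUES[int(rng.integers(len(RESIDUES)))],
            tuple(np.round(rng.uniform(0, extent, 3), 3)),
        )
        for _ in range(n)
    ]
    return structure_from_atoms(atoms)


def _offsets(adjacency: int) -> list[tuple[int, int, int]]:
    # independent derivation: Chebyshev-1 shell filtered by Manhattan distance
    limit = {6: 1, 18: 2, 26: 3}[adjacency]
    return [
        o
        for o in itertools.product((-1, 0, 1), repeat=3)
        if o != (0, 0, 0) and sum(map(abs, o)) <= limit
    ]


def brute_force_mould(structure: Structure, cell_size: float = 1.0,
                      adjacency: int = 26) -> set[tuple]:
    """Literal all-cells triple loop applying the mould rule.

    Returns {((cx, cy, cz) cell centre rounded to 1e-6, residue_name)}.
    """
    coords = structure.coordinates()
    origin = np.floor(coords.min(axis=0) - cell_size)
    cells: dict[tuple[int, int, int], list] = {}
    for atom in structure.atoms:
        idx = tuple(
            int(np.floor((p - o) / cell_size))
            for p, o in zip(atom.position, origin)
        )
        cells.setdefault(idx, []).append(atom)
    hi = np.max([list(c) for c in cells], axis=0)
    lo = np.min([list(c) for c in cells], axis=0)
    offsets = _offsets(adjacency)
    dummies = set()
    for ix in range(lo[0] - 1, hi[0] + 2):
        for iy in range(lo[1] - 1, hi[1] + 2):
            for iz in range(lo[2] - 1, hi[2] + 2):
                if (ix, iy, iz) in cells:
                    continue
                neighbours = []
                for dx, dy, dz in offsets:
                    neighbours.extend(cells.get((ix + dx, iy + dy, iz + dz), []))
                if len(neighbours) == 1:
                    centre = origin + (np.array([ix, iy, iz]) + 0.5) * cell_size
                    dummies.add(
                        (tuple(np.round(centre, 6)), neighbours[0].residue_name)
                    )
    return dummies


def mould_as_set(mould) -> set[tuple]:
    return {
        (tuple(np.round(d.position, 6)), d.residue_name) for d in mould.dummies
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def single_ala_pdb(tmp_path):
    path = tmp_path / "ala.pdb"
    path.write_text(make_toy_structure(ToySpec(atoms=[("ALA", (0.0, 0.0, 0.0))])))
    return path


@pytest.fixture
def two_cluster_pdb(tmp_path):
    """Two residues far apart: ARG cluster at the origin, GLU at +40 Å."""
    atoms = [
        ("ARG", (0.0, 0.0, 0.0)),
        ("ARG", (3.0, 0.0, 0.0)),
        ("GLU", (40.0, 0.0, 0.0)),
        ("GLU", (43.0, 0.0, 0.0)),
    ]
    path = tmp_path / "pair.pdb"
    path.write_text(make_toy_structure(ToySpec(atoms=atoms)))
    return path
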