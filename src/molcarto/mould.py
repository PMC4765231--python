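"""Occupancy grid and dummy-atom surface mould.

The structure is embedded in a cubic grid (1 Å cells by default). A dummy
atom is then placed at the centre of every *empty* cell whose neighbourhood
contains exactly one protein atom, and it inherits that atom's residue
identity. The resulting shell of dummies approximates the protein surface at
the resolution of residue atoms; empty cells crowding two or more atoms are
ambiguous and contribute nothing.

Neighbourhood adjacency defaults to the 26-cell Moore neighbourhood
(face + edge + corner); 6- and 18-connectivity are available, as is a
relaxed multiplicity rule that accepts any number of neighbouring atoms and
inherits from the nearest one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMouldError
from .pdb_io import Atom, Structure, serialize_pdb

__all__ = [
    "OccupancyGrid",
    "DummyAtom",
    "Mould",
    "build_grid",
    "generate_mould",
    "neighbour_offsets",
    "mould_to_pdb",
]

Cell = tuple[int, int, int]


def neighbour_offsets(adjacency: int = 26) -> list[Cell]:
    """Offsets of the 6-, 18- or 26-cell neighbourhood (excluding the origin).

    6 keeps face neighbours, 18 adds edges, 26 adds corners (Moore).
    """
    if adjacency not in (6, 18, 26):
        raise ValueError("adjacency must be 6, 18 or 26")
    max_manhattan = {6: 1, 18: 2, 26: 3}[adjacency]
    return [
        (dx, dy, dz)
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= max_manhattan
    ]


@dataclass
class OccupancyGrid:
    """A cubic grid over the structure with per-cell atom membership.

    ``origin`` is the floor of the structure's minimum coordinate minus one
    cell, so the grid always extends at least one cell beyond the atom
    bounding box and boundary cells can host dummies. Cell membership uses
    half-open intervals [lo, lo + cell_size) per axis.
    """

    origin: np.ndarray
    cell_size: float
    occupied: dict[Cell, list[Atom]]

    def cell_of(self, position: np.ndarray) -> Cell:
        idx = np.floor((np.asarray(position, dtype=float) - self.origin) / self.cell_size)
        return (int(idx[0]), int(idx[1]), int(idx[2]))

    def cell_centre(self, cell: Cell) -> np.ndarray:
        return self.origin + (np.array(cell, dtype=float) + 0.5) * self.cell_size


@dataclass(frozen=True)
class DummyAtom:
    """Pseudo-atom at an empty cell centre, carrying its neighbour's residue."""

    position: tuple[float, float, float]
    residue_name: str
    source_atom: Atom

    def __post_init__(self) -> None:
        assert self.residue_name == self.source_atom.residue_name


@dataclass
class Mould:
    """The dummy-atom shell approximating the protein surface."""

    dummies: list[DummyAtom]
    grid: OccupancyGrid

    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.dummies], dtype=float).reshape(-1, 3)

    def residues(self) -> list[str]:
        return [d.residue_name for d in self.dummies]


def build_grid(s: Structure, cell_size: float = 1.0) -> OccupancyGrid:
    """Embed the structure in a grid of cubic cells (1 Å by default)."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if not s.atoms:
        raise ValueError("cannot grid an empty structure")
    coords = s.coordinates()
    origin = np.floor(coords.min(axis=0) - cell_size)
    grid = OccupancyGrid(origin=origin, cell_size=cell_size, occupied={})
    for atom in s.atoms:
        grid.occupied.setdefault(grid.cell_of(atom.position), []).append(atom)
    return grid


def generate_mould(
    g: OccupancyGrid,
    adjacency: int = 26,
    multiplicity: str = "exactly-one",
) -> Mould:
    """Place dummy atoms in empty cells bordering the protein.

    With the default ``exactly-one`` rule an empty cell produces a dummy only
    when its neighbourhood contains exactly one protein atom (atoms counted,
    not cells), and the dummy inherits that atom's residue. The
    ``at-least-one-nearest`` rule accepts any occupied neighbourhood and
    inherits from the atom nearest to the cell centre (ties: first in input
    order).

    Raises
    ------
    EmptyMouldError
        If no cell satisfies the rule (e.g. every boundary cell sees two or
        more atoms).
    """
    if multiplicity not in ("exactly-one", "at-least-one-nearest"):
        raise ValueError("multiplicity must be 'exactly-one' or 'at-least-one-nearest'")
    if not g.occupied:
        raise ValueError("grid has no occupied cells")
    offsets = neighbour_offsets(adjacency)

    candidates: set[Cell] = set()
    for cx, cy, cz in g.occupied:
        for dx, dy, dz in offsets:
            cell = (cx + dx, cy + dy, cz + dz)
            if cell not in g.occupied:
                candidates.add(cell)

    dummies = []
    for cell in sorted(candidates):
        neighbours: list[Atom] = []
        for dx, dy, dz in offsets:
            neighbours.extend(
                g.occupied.get((cell[0] + dx, cell[1] + dy, cell[2] + dz), ())
            )
        if not neighbours:
            continue
        if multiplicity == "exactly-one":
            if len(neighbours) != 1:
                continue
            source = neighbours[0]
        else:
            centre = g.cell_centre(cell)
            source = min(
                neighbours,
                key=lambda a: float(np.sum((np.asarray(a.position) - centre) ** 2)),
            )
        centre = g.cell_centre(cell)
        dummies.append(
            DummyAtom(
                position=(float(centre[0]), float(centre[1]), float(centre[2])),
                residue_name=source.residue_name,
                source_atom=source,
            )
        )

    if not dummies:
        raise EmptyMouldError(
            "empty mould: no empty cell neighbours exactly one protein atom"
        )
    return Mould(dummies=dummies, grid=g)


def mould_to_pdb(m: Mould) -> str:
    """Debug dump of the mould as pseudo-atom PDB text (residues preserved)."""
    atoms = [
        Atom(
            serial=i + 1,
            name="DU",
            residue_name=d.residue_name,
            chain="A",
            residue_number=i + 1,
            position=d.position,
            element="X",
            is_hetero=True,
        )
        for i, d in enumerate(m.dummies)
    ]
    return serialize_pdb(Structure(atoms, source_id="mould"))
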