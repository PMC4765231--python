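"""Synthetic toy structures and frame series with known geometry.

Real surface maps need real proteins, but every stage of the cartography
pipeline is testable on hand-built atom clusters: the grid and mould rules
are exact set constructions, the sphere/projection steps are closed-form
geometry, and animations only need a short series of superposed frames.
This module writes such inputs as minimal, valid PDB text.

The frame series emulates a superposed molecular-dynamics trajectory as a
base structure plus independent isotropic Gaussian jitter per atom per frame
(no physical realism claimed — no bonding, no correlated motion, no solvent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pdb_io import Atom, Structure, serialize_pdb

__all__ = ["ToySpec", "make_toy_structure", "make_frame_series"]

Vec3 = tuple[float, float, float]


@dataclass
class ToySpec:
    """Recipe for a synthetic structure or frame series.

    ``atoms`` is an ordered list of ``(residue_name, (x, y, z))`` entries;
    consecutive entries sharing a residue name are grouped into one residue.
    ``jitter_sd`` is the per-axis standard deviation (Å) of the Gaussian
    displacement applied independently to every atom of every frame.
    """

    atoms: list[tuple[str, Vec3]]
    jitter_sd: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ToySpec.atoms must be non-empty")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def _to_structure(spec: ToySpec, coords: np.ndarray, source_id: str) -> Structure:
    atoms = []
    residue_number = 0
    prev_res = None
    for i, ((resname, _), xyz) in enumerate(zip(spec.atoms, coords)):
        if resname != prev_res:
            residue_number += 1
            prev_res = resname
        atoms.append(
            Atom(
                serial=i + 1,
                name="CA",
                residue_name=resname,
                chain="A",
                residue_number=residue_number,
                position=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                element="C",
            )
        )
    return Structure(atoms, source_id=source_id)


def make_toy_structure(spec: ToySpec) -> str:
    """Render the spec's base coordinates as PDB text (no jitter applied)."""
    coords = np.array([p for _, p in spec.atoms], dtype=float).reshape(-1, 3)
    return serialize_pdb(_to_structure(spec, coords, "toy"))


def make_frame_series(spec: ToySpec, directory: str | Path) -> list[Path]:
    """Write ``frame_<k>.pdb`` for k = 1..n_frames into *directory*.

    Frame k adds jitter drawn from a generator seeded with ``(seed, k)``, so
    output is reproducible bit-for-bit for equal seeds and each frame's
    content is independent of generation order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = np.array([p for _, p in spec.atoms], dtype=float).reshape(-1, 3)
    paths = []
    for k in range(1, spec.n_frames + 1):
        rng = np.random.default_rng([spec.seed, k])
        coords = base + rng.normal(0.0, spec.jitter_sd, size=base.shape)
        path = directory / f"frame_{k}.pdb"
        path.write_text(serialize_pdb(_to_structure(spec, coords, path.stem)))
        paths.append(path)
    return paths
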