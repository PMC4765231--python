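"""Single-frame orchestration: PDB -> mould -> sphere -> map -> values.

``run_frame`` composes the whole chain for one structure: parse and filter
the PDB, build the occupancy grid and the dummy-atom mould, push the mould
onto its bounding sphere, convert to latitude/longitude, apply the Miller
projection, annotate every point with its residue's descriptor value
(points whose residue the descriptor does not cover are dropped and
counted), and smooth. Each stage failure is re-raised naming the stage;
warnings from all stages are collected on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import mould as mould_mod
from . import pdb_io, projection, smoothing
from .errors import MolcartoError, MolcartoWarning, StageError
from .properties import DescriptorRegistry, default_registry, lookup
from .smoothing import PropertyField

__all__ = ["FrameOptions", "FrameResult", "run_frame"]


@dataclass
class FrameOptions:
    """Tunable parameters of the single-frame pipeline."""

    include_hetero: bool = False
    include_water: bool = False
    cell_size: float = 1.0  # Å
    adjacency: int = 26  # 6 | 18 | 26
    multiplicity: str = "exactly-one"
    smooth: bool = True
    smooth_min_cell: float = 0.001  # degrees
    smooth_max_cell: float = 0.5
    smooth_step: float = 0.001
    smoothing_space: str = "projected"  # projected | geographic
    smoothing_mode: str = "independent"  # independent | sequential
    on_unknown_residue: str = "skip"


@dataclass
class FrameResult:
    """Output of one frame: the annotated (and smoothed) property field."""

    source_id: str
    field: PropertyField
    raw_field: PropertyField
    dropped_points: int = 0
    warnings: list[str] = field(default_factory=list)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MolcartoError as exc:
        raise StageError(name, exc) from exc


def run_frame(
    pdb_path: str | Path,
    descriptor: str,
    registry: DescriptorRegistry | None = None,
    options: FrameOptions | None = None,
) -> FrameResult:
    """Run the full cartography pipeline on one PDB file."""
    options = options or FrameOptions()
    registry = registry if registry is not None else default_registry()
    pdb_path = Path(pdb_path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", MolcartoWarning)

        def read(p: Path):
            try:
                text = p.read_text()
            except OSError as exc:
                raise pdb_io.PdbParseError(f"cannot read {p}: {exc}") from exc
            return pdb_io.parse_pdb(text, source_id=p.stem)

        structure = _stage("parse", read, pdb_path)
        structure = _stage(
            "filter", pdb_io.filter_atoms, structure,
            options.include_hetero, options.include_water,
        )
        grid = _stage("grid", mould_mod.build_grid, structure, options.cell_size)
        m = _stage(
            "mould", mould_mod.generate_mould, grid,
            options.adjacency, options.multiplicity,
        )
        positions = m.positions()
        c = _stage("sphere", projection.centre_of_mass, positions)
        radius = _stage("sphere", projection.max_radius, positions, c)
        sphere = _stage(
            "sphere", projection.spherify, positions, c, radius, m.residues()
        )
        geo = _stage("project", projection.to_geographic, sphere)
        x, y = _stage("project", projection.miller_project, geo)

        per_residue = {
            res: _stage(
                "lookup", lookup, registry, descriptor, res,
                options.on_unknown_residue,
            )
            for res in dict.fromkeys(geo.residues)
        }
        point_values = [per_residue[r] for r in geo.residues]
        keep = np.array([v is not None for v in point_values], dtype=bool)
        values = np.array(
            [v if v is not None else np.nan for v in point_values], dtype=float
        )
        dropped = sphere.n_dropped + int((~keep).sum())
        if not keep.any():
            raise StageError(
                "lookup",
                MolcartoError(
                    f"descriptor {descriptor!r} covers none of the residues "
                    f"in {pdb_path.name}"
                ),
            )
        raw = PropertyField(
            x=x[keep],
            y=y[keep],
            values=values[keep],
            residues=[r for r, k in zip(geo.residues, keep) if k],
            descriptor_name=descriptor,
            smoothed=False,
        )
        if options.smooth:
            out = _stage(
                "smooth", smoothing.smooth, raw,
                options.smooth_min_cell, options.smooth_max_cell,
                options.smooth_step, options.smoothing_space,
                options.smoothing_mode,
            )
        else:
            out = raw

    return FrameResult(
        source_id=pdb_path.stem,
        field=out,
        raw_field=raw,
        dropped_points=dropped,
        warnings=[str(w.message) for w in caught],
    )
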