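"""Reading and writing PDB coordinate files.

Only the coordinate subset of the format is handled: ``ATOM``/``HETATM``
records plus ``MODEL``/``ENDMDL`` bookkeeping. Coordinates are read from the
fixed columns defined by the format (31-38, 39-46, 47-54), never by
whitespace splitting, so files with merged columns parse correctly.

Policy choices (documented in docs/methods.md):

* multi-model files keep the first model only and warn;
* alternate locations keep the highest-occupancy copy, ties broken by first
  occurrence;
* hydrogens are retained;
* water (HOH/WAT) and HETATM records are dropped by default at the filtering
  step, each behind a flag.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FilterError, FrameSeriesError, MolcartoWarning, PdbParseError

__all__ = [
    "Atom",
    "Structure",
    "parse_pdb",
    "filter_atoms",
    "ordered_frame_paths",
    "load_frame_series",
    "serialize_pdb",
]

_WATER_RESIDUES = frozenset({"HOH", "WAT"})


@dataclass(frozen=True)
class Atom:
    """One coordinate record of a PDB file."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    position: tuple[float, float, float]
    element: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass
class Structure:
    """An ordered collection of atoms from a single PDB model."""

    atoms: list[Atom]
    source_id: str = ""
    model_count_seen: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n, 3) float array of atom positions, in Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)


def _parse_float(text: str, what: str, lineno: int, source: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PdbParseError(
            f"{source}: malformed {what} field {text!r} on line {lineno}"
        ) from None


def parse_pdb(text: str | Iterable[str], source_id: str = "<stream>") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only the first model of a multi-model (NMR-style) file is kept; the total
    number of models seen is recorded and a warning emitted. Alternate
    locations of the same atom are resolved to the highest-occupancy copy.

    Raises
    ------
    PdbParseError
        If the input contains no coordinate records, or a coordinate/
        occupancy field does not parse as a number (the error names the
        offending line).
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    atoms: list[Atom] = []
    model_count = 0
    in_first_model = True
    for lineno, line in enumerate(lines, start=1):
        record = line[:6].strip()
        if record == "MODEL":
            model_count += 1
            in_first_model = model_count == 1
            continue
        if record == "ENDMDL":
            in_first_model = False
            continue
        if record not in ("ATOM", "HETATM") or not in_first_model:
            continue
        if len(line) < 54:
            raise PdbParseError(
                f"{source_id}: coordinate record too short on line {lineno}"
            )
        serial_txt = line[6:11].strip()
        serial = int(serial_txt) if serial_txt.lstrip("-").isdigit() else 0
        occ_txt = line[54:60].strip()
        atoms.append(
            Atom(
                serial=serial,
                name=line[12:16].strip(),
                residue_name=line[17:20].strip(),
                chain=line[21:22].strip(),
                residue_number=int(line[22:26].strip() or 0),
                position=(
                    _parse_float(line[30:38].strip(), "x coordinate", lineno, source_id),
                    _parse_float(line[38:46].strip(), "y coordinate", lineno, source_id),
                    _parse_float(line[46:54].strip(), "z coordinate", lineno, source_id),
                ),
                element=line[76:78].strip() if len(line) >= 78 else "",
                altloc=line[16:17].strip(),
                occupancy=_parse_float(occ_txt, "occupancy", lineno, source_id)
                if occ_txt
                else 1.0,
                is_hetero=record == "HETATM",
            )
        )

    if not atoms:
        raise PdbParseError(f"{source_id}: no ATOM/HETATM coordinate records found")

    model_count = max(model_count, 1)
    if model_count > 1:
        warnings.warn(
            f"{source_id}: {model_count} models found; keeping model 1 only",
            MolcartoWarning,
            stacklevel=2,
        )

    return Structure(
        atoms=_resolve_altlocs(atoms),
        source_id=source_id,
        model_count_seen=model_count,
    )


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """Keep the highest-occupancy alternate location per atom site.

    Ties go to the first occurrence. Atoms without an altloc code pass
    through untouched; order of the surviving atoms is preserved.
    """
    best: dict[tuple, int] = {}
    for i, atom in enumerate(atoms):
        if not atom.altloc:
            continue
        key = (atom.chain, atom.residue_number, atom.residue_name, atom.name)
        j = best.get(key)
        if j is None or atom.occupancy > atoms[j].occupancy:
            best[key] = i
    winners = set(best.values())
    return [
        a
        for i, a in enumerate(atoms)
        if not a.altloc
        or i in winners
    ]


def filter_atoms(
    s: Structure,
    include_hetero: bool = False,
    include_water: bool = False,
) -> Structure:
    """Apply the default atom-selection rules.

    HETATM records and water residues (HOH/WAT) are removed unless the
    corresponding flag is set; hydrogens are always retained. Order is
    preserved and the operation is idempotent.

    Raises
    ------
    FilterError
        If no atoms remain.
    """
    kept = []
    for a in s.atoms:
        if a.residue_name in _WATER_RESIDUES and not include_water:
            continue
        if a.is_hetero and a.residue_name not in _WATER_RESIDUES and not include_hetero:
            continue
        kept.append(a)
    if not kept:
        raise FilterError(f"{s.source_id}: no atoms remain after filtering")
    return Structure(kept, source_id=s.source_id, model_count_seen=s.model_count_seen)


_DIGITS = re.compile(r"(\d+)")


def _frame_index(stem: str) -> int | None:
    """Last run of digits in a file stem, or None."""
    runs = _DIGITS.findall(stem)
    return int(runs[-1]) if runs else None


def ordered_frame_paths(directory: str | Path) -> list[Path]:
    """``*.pdb`` paths in frame order.

    Frames are ordered by the last run of digits in each file stem (the
    convention of common MD exporters, e.g. ``frame_10.pdb``); when any file
    lacks digits the whole series falls back to lexicographic order with a
    warning. Duplicate frame indices are an error.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.pdb"))
    if not paths:
        raise FrameSeriesError(f"no .pdb files found in {directory}")

    indices = [_frame_index(p.stem) for p in paths]
    if all(i is not None for i in indices):
        if len(set(indices)) != len(indices):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise FrameSeriesError(
                f"duplicate frame indices {dupes} in {directory}"
            )
        paths = [p for _, p in sorted(zip(indices, paths), key=lambda t: t[0])]
    else:
        warnings.warn(
            f"{directory}: not all frame filenames carry an index; "
            "falling back to lexicographic order",
            MolcartoWarning,
            stacklevel=2,
        )
    return paths


def load_frame_series(
    directory: str | Path,
    include_hetero: bool = False,
    include_water: bool = False,
) -> list[Structure]:
    """Load every ``*.pdb`` file in *directory* as an ordered frame series.

    Ordering follows :func:`ordered_frame_paths`; each frame is parsed and
    filtered identically.
    """
    paths = ordered_frame_paths(directory)
    frames = []
    for p in paths:
        s = parse_pdb(p.read_text(), source_id=p.stem)
        frames.append(filter_atoms(s, include_hetero, include_water))
    return frames


def serialize_pdb(s: Structure) -> str:
    """Write a structure back out as minimal PDB text.

    Coordinates keep the format's 3-decimal precision, so
    ``parse_pdb(serialize_pdb(s))`` round-trips atom counts, residue names
    and coordinates to 0.001 Å.
    """
    lines = []
    for a in s.atoms:
        record = "HETATM" if a.is_hetero else "ATOM"
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"{record:<6s}{a.serial:>5d} {name:<4.4s}{a.altloc:1.1s}"
            f"{a.residue_name:>3s} {a.chain:1.1s}{a.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
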