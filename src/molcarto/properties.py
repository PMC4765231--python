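"""Per-amino-acid descriptor registry, SQLite persistence, and FASA_H.

A *descriptor* is a physicochemical property with one value per standard
amino acid (molecular weight, formal charge, hydrophobic surface fraction,
...). The registry stores such records grouped into 11 taxonomy categories;
surface maps colour every dummy atom by the value of its inherited residue
type, so the database is per-residue, never per-atom.

Persistence uses a single-file SQLite database with two tables::

    descriptors(name TEXT PRIMARY KEY, category TEXT, units TEXT,
                description TEXT)
    aa_values(descriptor_name TEXT, amino_acid TEXT, value REAL)

A descriptor with zero rows in ``aa_values`` is an *unpopulated* taxonomy
placeholder; anything between 1 and 19 amino acids is a schema error. A
user-supplied database fully replaces the default registry.
"""

from __future__ import annotations

import difflib
import sqlite3
import warnings
from dataclasses import dataclass
from pathlib import Path

from ._descriptor_names import (
    AMINO_ACIDS,
    ASA_HYDROPHOBIC,
    ASA_TOTAL,
    CATEGORY_COUNTS,
    CATEGORY_NAMES,
    FORMAL_CHARGE,
    FORMULAS,
    WEIGHT,
)
from .errors import (
    DatabaseError,
    MolcartoWarning,
    UnknownDescriptorError,
    UnpopulatedDescriptorError,
)

__all__ = [
    "AMINO_ACIDS",
    "DescriptorRecord",
    "DescriptorRegistry",
    "default_registry",
    "load_database",
    "write_database",
    "write_codebook",
    "lookup",
    "fasa_h",
]


@dataclass
class DescriptorRecord:
    """One descriptor: its category, units, and 20 per-amino-acid values.

    ``values`` is either a complete mapping over the 20 standard amino
    acids, or ``None`` for an unpopulated taxonomy placeholder.
    """

    name: str
    category: str
    values: dict[str, float] | None
    units: str = ""
    description: str = ""

    @property
    def populated(self) -> bool:
        return self.values is not None


@dataclass
class DescriptorRegistry:
    """Mapping of descriptor name -> record, plus the category taxonomy."""

    records: dict[str, DescriptorRecord]
    categories: tuple[tuple[str, int], ...] = CATEGORY_COUNTS

    def __len__(self) -> int:
        return len(self.records)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records.values():
            counts[rec.category] = counts.get(rec.category, 0) + 1
        return counts

    def populated_names(self) -> list[str]:
        return [n for n, r in self.records.items() if r.populated]


def fasa_h(asa_hydrophobic: float, asa_total: float) -> float:
    """Fraction of the water-accessible surface contributed by hydrophobic
    atoms: ASA(hydrophobic) / ASA(all), in [0, 1].
    """
    if asa_total <= 0:
        raise ValueError("asa_total must be positive")
    if not 0 <= asa_hydrophobic <= asa_total:
        raise ValueError("asa_hydrophobic must lie in [0, asa_total]")
    return asa_hydrophobic / asa_total


def _default_values() -> dict[str, tuple[dict[str, float], str, str]]:
    """name -> (values, units, description) for the populated descriptors."""
    out: dict[str, tuple[dict[str, float], str, str]] = {
        "Weight": (dict(WEIGHT), "g/mol", "Molecular weight of the free amino acid."),
        "FCharge": (dict(FORMAL_CHARGE), "e", "Formal side-chain charge at pH 7."),
        "ASA": (dict(ASA_TOTAL), "A^2",
                "Water-accessible surface area (Shrake-Rupley, 1.4 A probe, "
                "idealized residue geometry)."),
        "ASA_H": (dict(ASA_HYDROPHOBIC), "A^2",
                  "Water-accessible surface area of hydrophobic atoms "
                  "(C, S and their bonded hydrogens)."),
        "FASA_H": (
            {aa: round(fasa_h(ASA_HYDROPHOBIC[aa], ASA_TOTAL[aa]), 4)
             for aa in AMINO_ACIDS},
            "fraction",
            "Fraction of the water-accessible surface area contributed by "
            "hydrophobic atoms.",
        ),
    }
    element_counts = {
        "a_nC": "C", "a_nH": "H", "a_nN": "N", "a_nO": "O", "a_nS": "S",
    }
    for name, el in element_counts.items():
        out[name] = (
            {aa: float(f.get(el, 0)) for aa, f in FORMULAS.items()},
            "count", f"Number of {el} atoms in the free amino acid.",
        )
    out["a_count"] = (
        {aa: float(sum(f.values())) for aa, f in FORMULAS.items()},
        "count", "Total number of atoms in the free amino acid.",
    )
    out["a_heavy"] = (
        {aa: float(sum(n for el, n in f.items() if el != "H"))
         for aa, f in FORMULAS.items()},
        "count", "Number of heavy (non-hydrogen) atoms.",
    )
    return out


def default_registry() -> DescriptorRegistry:
    """The built-in registry: full 328-name taxonomy, open values where known."""
    populated = _default_values()
    records: dict[str, DescriptorRecord] = {}
    for category, names in CATEGORY_NAMES.items():
        for name in names:
            values, units, description = populated.get(name, (None, "", ""))
            records[name] = DescriptorRecord(
                name=name,
                category=category,
                values=values,
                units=units,
                description=description
                or f"{category} descriptor (unpopulated placeholder).",
            )
    return DescriptorRegistry(records=records)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS descriptors (
    name TEXT PRIMARY KEY,
    category TEXT NOT NULL,
    units TEXT DEFAULT '',
    description TEXT DEFAULT ''
);
CREATE TABLE IF NOT EXISTS aa_values (
    descriptor_name TEXT NOT NULL REFERENCES descriptors(name),
    amino_acid TEXT NOT NULL,
    value REAL NOT NULL,
    PRIMARY KEY (descriptor_name, amino_acid)
);
"""


def write_database(registry: DescriptorRegistry, path: str | Path) -> None:
    """Export the registry as a single-file SQLite database."""
    with sqlite3.connect(path) as con:
        con.executescript(_SCHEMA)
        con.execute("DELETE FROM aa_values")
        con.execute("DELETE FROM descriptors")
        for rec in registry.records.values():
            con.execute(
                "INSERT INTO descriptors (name, category, units, description) "
                "VALUES (?, ?, ?, ?)",
                (rec.name, rec.category, rec.units, rec.description),
            )
            if rec.values is not None:
                con.executemany(
                    "INSERT INTO aa_values (descriptor_name, amino_acid, value) "
                    "VALUES (?, ?, ?)",
                    [(rec.name, aa, rec.values[aa]) for aa in AMINO_ACIDS],
                )
        con.commit()


def load_database(path: str | Path | None = None) -> DescriptorRegistry:
    """Load a registry from an SQLite file, or the default when *path* is None.

    A user database fully replaces the default registry. Every descriptor
    must carry values for all and only the 20 standard amino acids, or no
    values at all (unpopulated placeholder); partial coverage is rejected.
    """
    if path is None:
        return default_registry()
    path = Path(path)
    if not path.is_file():
        raise DatabaseError(f"descriptor database not found: {path}")
    con = sqlite3.connect(path)
    try:
        try:
            rows = con.execute(
                "SELECT name, category, units, description FROM descriptors"
            ).fetchall()
            value_rows = con.execute(
                "SELECT descriptor_name, amino_acid, value FROM aa_values"
            ).fetchall()
        except sqlite3.Error as exc:
            raise DatabaseError(
                f"{path}: schema mismatch — expected tables "
                f"descriptors(name, category, units, description) and "
                f"aa_values(descriptor_name, amino_acid, value): {exc}"
            ) from exc
    finally:
        con.close()

    if not rows:
        raise DatabaseError(f"{path}: database contains no descriptors")

    values_by_name: dict[str, dict[str, float]] = {}
    for dname, aa, value in value_rows:
        values_by_name.setdefault(dname, {})[aa] = float(value)

    records: dict[str, DescriptorRecord] = {}
    for name, category, units, description in rows:
        if name in records:
            raise DatabaseError(f"{path}: duplicate descriptor name {name!r}")
        values = values_by_name.pop(name, None)
        if values is not None:
            missing = sorted(set(AMINO_ACIDS) - set(values))
            extra = sorted(set(values) - set(AMINO_ACIDS))
            if missing or extra:
                detail = []
                if missing:
                    detail.append(f"missing {', '.join(missing)}")
                if extra:
                    detail.append(f"unexpected {', '.join(extra)}")
                raise DatabaseError(
                    f"{path}: descriptor {name!r} must cover exactly the 20 "
                    f"standard amino acids ({'; '.join(detail)})"
                )
        records[name] = DescriptorRecord(
            name=name, category=category, values=values,
            units=units or "", description=description or "",
        )
    if values_by_name:
        orphans = ", ".join(sorted(values_by_name))
        raise DatabaseError(f"{path}: values for unregistered descriptors: {orphans}")
    return DescriptorRegistry(records=records, categories=CATEGORY_COUNTS)


def lookup(
    registry: DescriptorRegistry,
    descriptor: str,
    residue: str,
    on_unknown_residue: str = "skip",
) -> float | None:
    """Value of *descriptor* for a residue type.

    Unknown descriptors raise, listing near-matches. Non-standard residues
    (e.g. MSE) are skipped with a warning by default (``None`` returned), or
    raise with ``on_unknown_residue="error"``.
    """
    if on_unknown_residue not in ("skip", "error"):
        raise ValueError("on_unknown_residue must be 'skip' or 'error'")
    rec = registry.records.get(descriptor)
    if rec is None:
        near = difflib.get_close_matches(descriptor, registry.records, n=3)
        hint = f"; did you mean: {', '.join(near)}?" if near else ""
        raise UnknownDescriptorError(f"unknown descriptor {descriptor!r}{hint}")
    if not rec.populated:
        raise UnpopulatedDescriptorError(
            f"descriptor {descriptor!r} is registered in the taxonomy but "
            "carries no values in this registry; supply a database that "
            "populates it (see write_database) or pick a populated one: "
            + ", ".join(sorted(registry.populated_names()))
        )
    value = rec.values.get(residue)
    if value is None:
        if on_unknown_residue == "error":
            raise UnknownDescriptorError(
                f"residue {residue!r} has no value for descriptor {descriptor!r}"
            )
        warnings.warn(
            f"residue {residue!r} not covered by descriptor {descriptor!r}; skipped",
            MolcartoWarning,
            stacklevel=2,
        )
        return None
    return value


def write_codebook(registry: DescriptorRegistry, path: str | Path) -> None:
    """Plain-text codebook: every descriptor with category and description."""
    lines = ["# Descriptor codebook", ""]
    for category, _ in registry.categories:
        members = [r for r in registry.records.values() if r.category == category]
        if not members:
            continue
        lines.append(f"## {category} ({len(members)})")
        for rec in members:
            flag = "" if rec.populated else " [unpopulated]"
            units = f" ({rec.units})" if rec.units else ""
            lines.append(f"- {rec.name}{units}{flag}: {rec.description}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
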