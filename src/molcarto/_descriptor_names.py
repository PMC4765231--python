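"""Default descriptor registry: taxonomy and populated value tables.

The default registry replicates an 11-category taxonomy of 328 per-amino-
acid physicochemical descriptors, with names reconstructed from the widely
used molecular-descriptor families (topological indices, atom/bond counts,
conformation-dependent charge terms, Kier–Hall indices, semi-empirical
MOPAC quantities, partial-charge surface terms, pharmacophore features,
force-field energies, physical properties, subdivided surface areas, and
surface/volume/shape descriptors). Most descriptors require proprietary
software to evaluate and are registered *unpopulated*: they appear in the
taxonomy and the codebook but error on lookup. A subset is populated from
open sources:

* ``Weight`` — free amino-acid molecular weights (standard atomic masses);
* ``FCharge`` — formal side-chain charge at pH 7 (Asp/Glu −1, Lys/Arg +1);
* ``a_count``/``a_heavy``/``a_nC``/``a_nH``/``a_nN``/``a_nO``/``a_nS`` —
  derived here from the molecular formulas of the free amino acids;
* ``ASA``, ``ASA_H``, ``FASA_H`` — water-accessible surface areas computed
  with the Shrake–Rupley algorithm (1.4 Å probe) over idealized residue
  geometries from the chemical component dictionary; hydrophobic atoms are
  C and S plus their bonded hydrogens. Regenerate with
  ``scripts/build_asa_values.py``.
"""

from __future__ import annotations

AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: The 11 taxonomy categories with their expected descriptor counts.
CATEGORY_COUNTS: tuple[tuple[str, int], ...] = (
    ("adjacency and distance matrix", 33),
    ("atom and bond counts", 41),
    ("conformation dependent charge", 18),
    ("Kier and Hall connectivity and kappa shape indices", 16),
    ("MOPAC", 21),
    ("partial charge", 48),
    ("pharmacophore features", 12),
    ("potential energy", 11),
    ("physical properties", 16),
    ("subdivided surface areas", 18),
    ("surface area, volume and shape", 94),
)


def _series(prefix: str, n: int, start: int = 0) -> list[str]:
    return [f"{prefix}{i}" for i in range(start, start + n)]


CATEGORY_NAMES: dict[str, list[str]] = {
    "adjacency and distance matrix": (
        ["balabanJ", "diameter", "petitjean", "radius",
         "VAdjEq", "VDistEq", "VDistMa", "weinerPath", "weinerPol"]
        + _series("BCUT_PEOE_", 4) + _series("BCUT_SLOGP_", 4)
        + _series("BCUT_SMR_", 4)
        + _series("GCUT_PEOE_", 4) + _series("GCUT_SLOGP_", 4)
        + _series("GCUT_SMR_", 4)
    ),
    "atom and bond counts": [
        "a_aro", "a_count", "a_heavy", "a_IC", "a_ICM",
        "a_nB", "a_nBr", "a_nC", "a_nCl", "a_nF", "a_nH", "a_nI",
        "a_nN", "a_nO", "a_nP", "a_nS", "a_nSi",
        "b_1rotN", "b_1rotR", "b_ar", "b_count", "b_double", "b_heavy",
        "b_max1len", "b_rotN", "b_rotR", "b_single", "b_triple",
        "chiral", "chiral_u",
        "lip_acc", "lip_don", "lip_druglike", "lip_violation",
        "opr_brigid", "opr_leadlike", "opr_nring", "opr_nrot", "opr_violation",
        "rings", "nmol",
    ],
    "conformation dependent charge": [
        "ASA+", "ASA-", "ASA_P", "CASA+", "CASA-", "CASA_P",
        "DASA", "DCASA", "DASA_H",
        "FASA+", "FASA-", "FASA_P", "FCASA+", "FCASA-",
        "dipole", "dipoleX", "dipoleY", "dipoleZ",
    ],
    "Kier and Hall connectivity and kappa shape indices": [
        "chi0", "chi0_C", "chi0v", "chi0v_C",
        "chi1", "chi1_C", "chi1v", "chi1v_C",
        "Kier1", "Kier2", "Kier3", "KierA1", "KierA2", "KierA3",
        "KierFlex", "zagreb",
    ],
    "MOPAC": [
        f"{method}_{quantity}"
        for method in ("AM1", "PM3", "MNDO")
        for quantity in ("dipole", "E", "Eele", "HF", "HOMO", "IP", "LUMO")
    ],
    "partial charge": (
        ["PEOE_PC+", "PEOE_PC-", "PEOE_RPC+", "PEOE_RPC-"]
        + [f"PEOE_VSA+{i}" for i in range(7)]
        + [f"PEOE_VSA-{i}" for i in range(7)]
        + ["PEOE_VSA_FHYD", "PEOE_VSA_FNEG", "PEOE_VSA_FPNEG", "PEOE_VSA_FPOL",
           "PEOE_VSA_FPOS", "PEOE_VSA_FPPOS", "PEOE_VSA_HYD", "PEOE_VSA_NEG",
           "PEOE_VSA_PNEG", "PEOE_VSA_POL", "PEOE_VSA_POS", "PEOE_VSA_PPOS"]
        + ["Q_PC+", "Q_PC-", "Q_RPC+", "Q_RPC-"]
        + ["Q_VSA_FHYD", "Q_VSA_FNEG", "Q_VSA_FPNEG", "Q_VSA_FPOL",
           "Q_VSA_FPOS", "Q_VSA_FPPOS", "Q_VSA_HYD", "Q_VSA_NEG",
           "Q_VSA_PNEG", "Q_VSA_POL", "Q_VSA_POS", "Q_VSA_PPOS"]
        + ["RPC+", "RPC-"]
    ),
    "pharmacophore features": [
        "a_acc", "a_acid", "a_base", "a_don", "a_donacc", "a_hyd",
        "vsa_acc", "vsa_acid", "vsa_base", "vsa_don", "vsa_hyd", "vsa_other",
    ],
    "potential energy": [
        "E", "E_ang", "E_ele", "E_nb", "E_oop", "E_sol",
        "E_stb", "E_str", "E_strain", "E_tor", "E_vdw",
    ],
    "physical properties": [
        "apol", "bpol", "density", "FCharge", "logP(o/w)", "logS",
        "mr", "mutagenic", "reactive", "rsynth", "SlogP", "SMR",
        "TPSA", "Weight", "h_logP", "h_logS",
    ],
    "subdivided surface areas": _series("SlogP_VSA", 10) + _series("SMR_VSA", 8),
    "surface area, volume and shape": (
        ["ASA", "ASA_H", "FASA_H", "glob", "npr1", "npr2",
         "pmi", "pmi1", "pmi2", "pmi3", "rgyr",
         "std_dim1", "std_dim2", "std_dim3", "vol", "VSA",
         "vdw_area", "vdw_vol",
         "vsurf_A", "vsurf_CP", "vsurf_G", "vsurf_R", "vsurf_S", "vsurf_V",
         "vsurf_DD12", "vsurf_DD13", "vsurf_DD23",
         "vsurf_DW12", "vsurf_DW13", "vsurf_DW23",
         "vsurf_HL1", "vsurf_HL2"]
        + _series("vsurf_CW", 8, start=1) + _series("vsurf_D", 8, start=1)
        + _series("vsurf_EDmin", 3, start=1) + _series("vsurf_EWmin", 3, start=1)
        + _series("vsurf_HB", 8, start=1) + _series("vsurf_ID", 8, start=1)
        + _series("vsurf_IW", 8, start=1) + _series("vsurf_W", 8, start=1)
        + _series("vsurf_Wp", 8, start=1)
    ),
}

for _label, _count in CATEGORY_COUNTS:
    assert len(CATEGORY_NAMES[_label]) == _count, (
        _label, len(CATEGORY_NAMES[_label]), _count)
    assert len(set(CATEGORY_NAMES[_label])) == _count, _label

# ---------------------------------------------------------------------------
# populated value tables (open sources; see module docstring)
# ---------------------------------------------------------------------------

#: Molecular formulas of the free amino acids.
FORMULAS: dict[str, dict[str, int]] = {
    "ALA": {"C": 3, "H": 7, "N": 1, "O": 2},
    "ARG": {"C": 6, "H": 14, "N": 4, "O": 2},
    "ASN": {"C": 4, "H": 8, "N": 2, "O": 3},
    "ASP": {"C": 4, "H": 7, "N": 1, "O": 4},
    "CYS": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "GLN": {"C": 5, "H": 10, "N": 2, "O": 3},
    "GLU": {"C": 5, "H": 9, "N": 1, "O": 4},
    "GLY": {"C": 2, "H": 5, "N": 1, "O": 2},
    "HIS": {"C": 6, "H": 9, "N": 3, "O": 2},
    "ILE": {"C": 6, "H": 13, "N": 1, "O": 2},
    "LEU": {"C": 6, "H": 13, "N": 1, "O": 2},
    "LYS": {"C": 6, "H": 14, "N": 2, "O": 2},
    "MET": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "PHE": {"C": 9, "H": 11, "N": 1, "O": 2},
    "PRO": {"C": 5, "H": 9, "N": 1, "O": 2},
    "SER": {"C": 3, "H": 7, "N": 1, "O": 3},
    "THR": {"C": 4, "H": 9, "N": 1, "O": 3},
    "TRP": {"C": 11, "H": 12, "N": 2, "O": 2},
    "TYR": {"C": 9, "H": 11, "N": 1, "O": 3},
    "VAL": {"C": 5, "H": 11, "N": 1, "O": 2},
}

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

WEIGHT: dict[str, float] = {
    aa: round(sum(_ATOMIC_MASS[el] * n for el, n in formula.items()), 2)
    for aa, formula in FORMULAS.items()
}

FORMAL_CHARGE: dict[str, float] = {
    aa: {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}.get(aa, 0.0)
    for aa in AMINO_ACIDS
}

# Shrake-Rupley, 1.4 A probe, idealized residue geometries (see docstring).
ASA_TOTAL: dict[str, float] = {
    "ALA": 240.91, "ARG": 385.10, "ASN": 295.45, "ASP": 291.48, "CYS": 272.13,
    "GLN": 321.45, "GLU": 320.27, "GLY": 216.85, "HIS": 331.69, "ILE": 307.15,
    "LEU": 312.84, "LYS": 353.92, "MET": 331.53, "PHE": 348.76, "PRO": 281.03,
    "SER": 258.51, "THR": 275.11, "TRP": 394.21, "TYR": 366.62, "VAL": 282.38,
}
ASA_HYDROPHOBIC: dict[str, float] = {
    "ALA": 91.95, "ARG": 115.48, "ASN": 57.04, "ASP": 60.07, "CYS": 131.79,
    "GLN": 80.08, "GLU": 83.21, "GLY": 56.32, "HIS": 135.84, "ILE": 174.14,
    "LEU": 175.13, "LYS": 141.69, "MET": 191.73, "PHE": 215.30, "PRO": 157.26,
    "SER": 60.07, "THR": 102.91, "TRP": 228.51, "TYR": 176.30, "VAL": 152.41,
}
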