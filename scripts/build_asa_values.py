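"""Regenerate the frozen ASA / ASA_H tables used by the default registry.

Computes water-accessible surface areas for the 20 standard amino acids with
the Shrake–Rupley algorithm (1.4 Å probe, 1000 sphere points) over the
idealized residue geometries of the chemical component dictionary bundled
with biotite. Hydrophobic atoms are carbons and sulfurs together with their
bonded hydrogens; ASA_H is their summed area.

Run from the repository root:

    python scripts/build_asa_values.py

and paste the printed dictionaries into src/molcarto/_descriptor_names.py.
Requires biotite (not a runtime dependency of the package).
"""

import numpy as np
import biotite.structure as struc
import biotite.structure.info as info

AAS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


def main() -> None:
    asa_total, asa_hydrophobic = {}, {}
    for aa in AAS:
        res = info.residue(aa)
        sasa = struc.sasa(res, probe_radius=1.4, point_number=1000, vdw_radii="Single")
        hydrophobic = np.isin(res.element, ["C", "S"])
        # hydrogens inherit the polarity of the heavy atom they bond to
        bonds, _ = res.bonds.get_all_bonds()
        for i in np.where(res.element == "H")[0]:
            partners = [j for j in bonds[i] if j != -1]
            if partners and res.element[partners[0]] in ("C", "S"):
                hydrophobic[i] = True
        asa_total[aa] = round(float(sasa.sum()), 2)
        asa_hydrophobic[aa] = round(float(sasa[hydrophobic].sum()), 2)
    print("_ASA_TOTAL =", asa_total)
    print("_ASA_HYDROPHOBIC =", asa_hydrophobic)


if __name__ == "__main__":
    main()
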