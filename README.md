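# molcarto

2D molecular cartography of protein surfaces.

Comparing the surfaces of proteins — across a molecular-dynamics
trajectory, between evolutionary relatives, or before/after a mutation —
is awkward in 3D: you can only see one side at a time, and physicochemical
patterns (charge patches, hydrophobic faces) are hard to quantify by
rotating a model. `molcarto` flattens the whole surface into a single 2D
map coloured by any per-amino-acid physicochemical descriptor, and turns a
series of superposed structures into a GIF animation, one map per frame.
It is aimed at structural bioinformaticians who want a reproducible,
scriptable surface fingerprint from nothing more than PDB files.

## The algorithm

For a structure with atoms at positions vᵢ:

1. **Mould** — embed the structure in a 1 Å cubic grid and put a *dummy
   atom* at the centre of every empty cell whose 26-cell neighbourhood
   contains exactly one protein atom; the dummy inherits that atom's
   residue identity. The dummies form a shell approximating the surface.
2. **Sphere** — with c = (1/n)Σvᵢ over mould points and
   radius = maxᵢ‖vᵢ − c‖, map every centred point onto the sphere:
   wᵢ = radius·(vᵢ − c)/‖vᵢ − c‖.
3. **Map** — convert each wᵢ to latitude/longitude
   (φ = arctan2(z, √(x²+y²)), λ = arctan2(y, x)) and apply the Miller
   cylindrical projection:

       x = λ,   y = (5/4) · ln tan(π/4 + (2/5)·φ)

4. **Colour** — give every map point the descriptor value of its residue
   type, drawn from a registry of 328 descriptors in 11 categories (SQLite
   file; user-replaceable). The populated built-ins include molecular
   weight, formal charge, atom counts, and the hydrophobic
   surface-area fraction FASA_H = ASA_hydrophobic / ASA_total.
5. **Smooth** — re-bin the map at square cell sizes 0.001°…0.5° in 0.001°
   steps; a point's final value is the mean over scales of its cell's mean
   raw value. This turns salt-and-pepper "dipoles" into readable regions.

See `docs/methods.md` for the full model description, parameter table and
limitations.

## Worked example

Generate a synthetic two-cluster peptide and map it:

```python
import numpy as np
from pathlib import Path
from molcarto import ToySpec, run_frame
from molcarto.fixtures import make_toy_structure

atoms = [("ARG", (0.0, 0.0, 0.0)), ("ARG", (2.0, 0.0, 0.0)),
         ("GLU", (8.0, 0.0, 0.0)), ("GLU", (10.0, 0.0, 0.0))]
Path("dipep.pdb").write_text(make_toy_structure(ToySpec(atoms=atoms)))

r = run_frame("dipep.pdb", "FASA_H")
print("map points:", len(r.field))
print("raw values:", sorted(set(np.round(r.raw_field.values, 4))))
print("smoothed range: [%.4f, %.4f]" % (r.field.values.min(),
                                        r.field.values.max()))
```

prints

```
map points: 68
raw values: [0.2598, 0.2999]
smoothed range: [0.2598, 0.2999]
```

68 dummy atoms survive the mould rule for these four atoms; the two raw
values are the FASA_H of arginine (0.2999) and glutamate (0.2598) — both
charged residues with mostly polar surfaces, ARG slightly the more
hydrophobic because of its longer aliphatic stalk. Smoothing stays within
the raw range by construction; points far apart on the map keep their raw
values, co-binned neighbours are averaged.

The same from the shell, including an animation:

```sh
molcarto-demo --outdir demo --n-frames 4 --seed 1   # synthetic frame series
molcarto-frame demo/frame_1.pdb --property FASA_H --outdir maps --verbose
#   frame_1: 63 map points, 0 dropped, 0.15s
#   maps/frame_1.tif
molcarto demo --property FASA_H --outdir anim --cores 2 --delay 150 --keep-frames
#   anim/animation.gif
```

`molcarto` distributes whole frames across workers; the GIF is
byte-identical whatever `--cores` is. Frames share one colour scale so
colours are comparable across the animation.

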