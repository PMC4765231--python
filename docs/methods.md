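# Methods

## The cartographic model

`molcarto` represents the surface of a protein as a 2D map coloured by a
per-amino-acid physicochemical descriptor. The chain of transformations is:

1. **Surface mould.** The structure is embedded in a cubic grid (cell size
   1 Å by default). One *dummy atom* is placed at the centre of every empty
   grid cell whose neighbourhood contains exactly one protein atom, and the
   dummy inherits that atom's residue identity. The result is a shell of
   pseudo-atoms hugging the structure at the resolution of residue atoms.
   This is a voxel approximation of the surface, not a solvent-excluded
   (Connolly) surface: there is no probe rolling and no triangulation.
2. **Spherical mapping.** With c the unweighted mean position of the mould
   and `radius` the largest distance of any dummy from c, every centred
   dummy v′ᵢ = vᵢ − c is scaled to wᵢ = radius·v′ᵢ/‖v′ᵢ‖. All mould points
   end up on one sphere; radial (depth) information is deliberately
   discarded.
3. **Geographic conversion and projection.** Each wᵢ becomes latitude
   φ = arctan2(z, √(x²+y²)) and longitude λ = arctan2(y, x), then is
   flattened with the Miller cylindrical projection
   x = λ, y = (5/4)·ln tan(π/4 + (2/5)φ). The projection shows the whole
   sphere including the poles; distortion is zero at the equator and
   maximal but finite at the poles (|y| ≤ (5/4)·ln tan(9π/20) ≈ 2.3034).
4. **Value annotation.** Every map point receives the descriptor value of
   its residue *type* from the registry (the database is per-amino-acid,
   never per-atom).
5. **Smoothing.** The map is re-binned into square cells of side s for
   every s in 0.001°, 0.002°, …, 0.5° (500 scales); at each scale a cell
   carries the mean of the raw values inside it, and a point's final value
   is the mean of its cell value across scales. This suppresses single-point
   "hot spots" so regions of genuinely concentrated high or low values stand
   out.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `cell_size` | 1.0 | Å | mould grid resolution |
| `adjacency` | 26 | — | neighbourhood used by the mould rule (6/18/26) |
| `multiplicity` | exactly-one | — | or `at-least-one-nearest` |
| `smooth_min_cell` / `smooth_max_cell` / `smooth_step` | 0.001 / 0.5 / 0.001 | degrees | the smoothing ladder |
| `smoothing_space` | projected | — | bin on Miller (x, y) or on (λ, φ) degrees |
| `smoothing_mode` | independent | — | scales average raw values; `sequential` chains them |
| `delay_ms` | 100 | ms | GIF inter-frame delay |
| `value_range` | data min/max | descriptor units | shared across animation frames |

Design choices made where the method itself is underdetermined:

- **Adjacency.** "Neighbouring" cells are the 26-cell Moore neighbourhood:
  it is the common voxel convention and yields the tightest closed shell
  (exactly 26 dummies) around an isolated atom. 6- and 18-connectivity are
  selectable.
- **Multiplicity.** An empty cell produces a dummy only when it sees
  *exactly one* protein atom; cells crowding several atoms are ambiguous
  and yield nothing. The relaxed rule (any number, inherit from the
  nearest) is available for dense structures whose strict mould would be
  empty.
- **Grid anchoring.** The grid origin is the componentwise floor of the
  minimum coordinate minus one cell. This is deterministic and makes the
  mould exactly covariant under whole-cell translations. Fractional
  translations change grid registration and therefore the mould slightly —
  an inherent property of any fixed-grid method; maps of structures to be
  compared should come from superposed coordinates, which is also why
  frame series are assumed pre-superposed.
- **Centre of mass** is the unweighted average of mould dummy positions
  (no atomic masses), computed at the mould stage.
- **Longitude** uses the two-argument arctangent. A single-argument
  arctan(y/x) cannot distinguish hemispheres and would fold the map onto
  half its width; points on the polar axis get longitude 0 by convention.
- **Polar axis.** The input z-axis is the polar axis; maps are
  orientation-dependent by design, exactly as orientation is meaningful
  only between superposed structures.
- **Smoothing units.** The ladder is stated in degrees while the Miller
  ordinate is a pure number; smoothing therefore operates on
  (λ·180/π, y·180/π) so one "degree" means the same metric on both axes.
  A `geographic` switch bins on latitude degrees instead (the inverse
  Miller formula recovers φ from y in closed form).
- **Independent scales.** Every scale averages the *raw* values; the final
  value is the mean over scales. Chaining each scale's output into the next
  (`sequential`) is closer to iterative diffusion and is available for
  comparison, but is not the default because the per-scale cell means are
  defined on the data points themselves.
- **Bin anchoring and ties.** Bins are `floor(u/s)`, anchored at
  coordinate 0 and independent of data extent; a point exactly on a bin
  boundary belongs to the higher-index bin. Scales are formed from integer
  thousandths of a degree so the 500-term ladder accumulates no
  floating-point drift. The grid does not wrap across the ±180° seam —
  values on opposite sides of the seam never co-bin, a known edge artefact.

## Numerical behaviour and degenerate inputs

- Sphere radii are exact to ~1 ulp (‖wᵢ‖/radius − 1 ≲ 2·10⁻¹⁶); geometry
  tests use a 10⁻⁹ tolerance throughout.
- Mould points coincident with the centre of mass have no direction and
  are dropped with a warning (counted on the result); a mould whose every
  point coincides with c is an error.
- A structure whose every boundary cell sees ≥2 atoms yields an "empty
  mould" error under the strict rule.
- Multi-model (NMR-style) PDB files keep model 1 only, with a warning;
  alternate locations keep the highest-occupancy copy (ties: first
  occurrence); hydrogens are kept; HETATM and waters are dropped by
  default, each behind a flag. Coordinates are read from the fixed PDB
  columns, so merged-column files parse correctly.
- Smoothing is order-independent (group means), leaves constant fields
  exactly fixed, and keeps every output within the raw value range.

## Descriptor registry

The default registry contains 328 descriptor names in 11 categories
(33 adjacency/distance-matrix, 41 atom/bond-count, 18 conformation-
dependent-charge, 16 Kier–Hall, 21 MOPAC, 48 partial-charge,
12 pharmacophore, 11 potential-energy, 16 physical-property,
18 subdivided-surface-area, 94 surface/volume/shape). Most of these
quantities are conventionally computed with proprietary modelling
software; the registry therefore ships them as *unpopulated* taxonomy
placeholders that error on lookup with a pointer to the populated subset.
Twelve descriptors carry values from open sources: molecular weight
(standard atomic masses), formal charge at pH 7, seven atom-count
descriptors derived from the molecular formulas, and `ASA`/`ASA_H`/
`FASA_H` computed with the Shrake–Rupley algorithm (1.4 Å probe) over
idealized residue geometries, where hydrophobic atoms are carbons and
sulfurs with their bonded hydrogens and

    FASA_H = ASA(hydrophobic atoms) / ASA(all atoms).

`scripts/build_asa_values.py` regenerates the frozen ASA tables. Users can
replace the whole registry with their own SQLite file (two tables:
`descriptors(name, category, units, description)` and
`aa_values(descriptor_name, amino_acid, value)`); every populated
descriptor must cover all and only the 20 standard amino acids.
`write_codebook` emits a plain-text codebook of the active registry.

## Synthetic data

The `fixtures` module generates the test inputs: toy structures from
explicit (residue, position) lists, and frame series that add independent
isotropic Gaussian jitter (default series: a few atoms, 0.1 Å sd) to a base
structure, seeded per frame so output is byte-reproducible and
order-independent. This emulates only the *bookkeeping* of a superposed
molecular-dynamics trajectory — small uncorrelated positional noise — and
none of the physics (bonding, correlated motions, solvent, side-chain
packing). Tests passing on these fixtures therefore validate the geometry,
bookkeeping and determinism of the pipeline, not the biological
interpretability of maps of real proteins.

Problem sizes used by the test suite and the acceptance script — random
clusters of ≤30 atoms against a literal all-cells mould oracle (50
structures), 200-point fields against a pairwise smoothing oracle with a
5-scale ladder, 500-point sphere checks, and 4-frame animations at 60 dpi —
are chosen to exercise every code path at desk scale while the full
0.001°–0.5° ladder is still run wherever the scale count itself matters.

## Rendering and parallelism

Frames are drawn as square point markers (no antialiasing) on fixed axes
spanning the full Miller extent, with a two-colour linear gradient;
identical input and configuration give byte-identical files. Animations
distribute *whole frames* across a worker pool; because each frame depends
only on (input, configuration) and GIF assembly is serial and ordered, the
output is byte-identical regardless of worker count. Colour normalization
is global across frames by default (per-frame scaling is available but
makes colours incomparable between frames). The GIF encoder coalesces
consecutive identical frames, summing their delays.

## Known limitations

- The mould is a voxel shell, not a solvent-accessible surface; deep
  pockets whose voxels see several atoms are not represented.
- Radial scaling to a single sphere discards depth; two surfaces at
  different radii along the same ray collapse onto one point.
- Polar distortion of the Miller projection overstates distances near the
  poles of the chosen axis.
- Smoothing does not wrap across the map seam.
- Maps are orientation-dependent; only superposed structures are
  comparable.
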