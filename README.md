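# gvshell

Parametric modelling and analysis of gas-vesicle (GV) protein shells.

Gas vesicles are gas-filled, protein-walled nanocompartments whose wall is a
helical lattice of small monomers. This package builds complete
pseudo-atomic shell models from a single monomer and implements the
companion analyses:

- **`gvshell.geometry`** — closed-form helix calculus: pitch/units-per-turn
  vs. rise/twist conversions, the piecewise cylinder-plus-cone parametric
  curve, arc lengths (adaptive quadrature + inversion), inter-monomer
  spacing, diameter↔polymorph conversions with error propagation, and small
  identities for wall mechanics (magic angle, inter-strand H-bond angle) and
  accessory-repeat geometry.
- **`gvshell.builder`** — shell construction: arc-equidistant placement of
  monomer copies on the curve, rigid frame transport, four correction
  rotations about residue-indexed landmark atoms (pivot O28/O42, carbonyl
  O36, least-squares planes through CA 23–49 / CB 24–33, CA23–CA49 hinge),
  D1 duplication into a complete vesicle, helical-symmetry expansion,
  clash reporting, mass, and PDB/mmCIF export (via biotite).
- **`gvshell.projection`** — 2D projection images, across-tube width
  profiles with rim-peak detection and polymorph ladders, and cumulative
  in-plane-rotated power spectra with first-layer-line readout.
- **`gvshell.pore`** — grid-based widest-path ("bottleneck") search through
  a scene of van-der-Waals spheres; reports the diameter of the largest
  sphere that can traverse the route.
- **`gvshell.collapse`** — collapse-pressure curves: min–max OD
  normalization, bounded least-squares fit of the decreasing logistic
  `1/(1+exp(k(p−p0)))`, and n-of-n bootstrap uncertainty for `p0`.
- **`gvshell.synth`** — deterministic synthetic ground truth: a
  landmark-complete toy monomer, noisy collapse curves, cylinder/lattice
  projection images, and analytic slit scenes for the pore search.

## CLI

The `gvshell` entry point exposes one subcommand per analysis:

```sh
gvshell geometry                         # symmetry table + polymorph grid
gvshell build --full --out vesicle.cif --table placements.tsv
gvshell synth --what cylinder --out tube.mrc --diameter 356 --noise 0.1
gvshell widths tube.mrc                  # rim distance + polymorph ladder
gvshell synth --what lattice --out lat.mrc --noise 0
gvshell layerlines lat.mrc               # first layer-line spacing
gvshell synth --what slit --out slit.tsv --gap 10
gvshell pore slit.tsv --start 0,0,-8 --end 0,0,8 \
    --box-min -7,-12,-9 --box-max 7,12,9
gvshell synth --what collapse --out collapse.tsv --p0 5.2 --k 2
gvshell collapse-fit collapse.tsv --nboot 50 --seed 0
```

`build` defaults reproduce the reference model: radius 178.4 Å, pitch
48.8 Å, 25° cone, 5 cylindrical turns, 12.07 Å spacing, 4 tip points
omitted — 865 monomers per half shell, 1730 in the complete vesicle.
Complete vesicles are written as mmCIF (multi-letter chain IDs); small
segments may be written as PDB.

Images are read/written as MRC (mode 2, minimal built-in reader/writer) or
PNG previews.

## Conventions

- Lengths in Å (nm accepted at diameter-facing interfaces), angles in
  degrees. Cylinder axis = z, two-fold (D1) axis = x, curve phase t = 0 on
  +x. Left-handedness is encoded by negative twist and the minus sign in
  y(t).
- Monomer templates are expected in the canonical seed pose (pivot at
  (r_max, 0, 0)); `align_curve_to_pivot` seats arbitrary poses via z-shift
  and z-rotation.
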