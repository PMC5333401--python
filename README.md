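# phytoscreen

Desk-scale root and shoot phenotyping for gel-well ("Phytostrip")
seedling screens.

Miniaturised chemical screens grow *Arabidopsis* seedlings in strips of
eight flat, 2 mm-thick, 22 mm-deep transparent gel wells seated in
96-well microtitre plates.  Compounds added to the liquid below diffuse
up through the gel; a robot photographs every strip daily from the side
(roots on matt black) and from above (shoots on white).  `phytoscreen`
provides the downstream quantitative machinery for that kind of
platform:

* **probabilistic root traits** — each side-view pixel gets a root
  likelihood in [0, 1]; *root mass* is the summed likelihood (an expected
  root-pixel count), and a 4 × 4 matrix splits that mass by well quadrant
  (Q0 top … Q3 bottom) and orientation bin (22.5° classes of the angle
  from horizontal).  *Q0-horizontal* (top quadrant, 0–22.5°) tracks root
  hairs and lateral branching; *Q3-vertical* (bottom quadrant,
  67.5–90°) tracks primary-root extension;
* **shoot traits** — projected *leaf area* (coloured-pixel count against
  the white background) and *leaf hue* on a bounded red(0)–green(120)
  axis, a brightness-invariant greenness indicator;
* **a seeded Phytostrip simulator** — grows root systems as a
  gravitropism/tortuosity-controlled random walk with laterals and root
  hairs, renders side and overhead views, and keeps exact per-pixel
  ground truth (coverage, tangent orientation, shoot mask), so every
  analysis stage is testable without a robot;
* **screen bookkeeping** — plate/strip/well layout and capacity
  arithmetic, the `PlateA4_Strip9_Side` filename convention,
  equilibrium dilution of compounds into the gel, replicate time-course
  aggregation (mean ± SE), and control-deviation flagging.

## Worked example

Simulate a one-plate experiment, extract traits, and aggregate:

```bash
phytoscreen simulate --out demo --n-plates 1 --sessions 1 --seed 7
phytoscreen analyze --images demo --out demo/traits.csv
phytoscreen aggregate --traits demo/traits.csv --plate-map demo/plate_map.csv \
    --out demo/aggregates.csv
```

or from Python:

```python
>>> from phytoscreen.simulate import phenotype_preset, simulate_root_system, render_side_view
>>> from phytoscreen.roots import analyze_side_well
>>> system = simulate_root_system(phenotype_preset("control"), seed=42)
>>> rendered = render_side_view(system, noise_sd=0.02, seed=0)
>>> traits = analyze_side_well(rendered.image)
>>> round(traits.root_mass, 1)
5412.6
>>> round(traits.q0_horizontal, 1)
682.1
>>> round(traits.q3_vertical, 1)
0.0
```

`root_mass` ≈ 5413 is the expected number of root pixels in this
7-day-old two-seedling well; `q0_horizontal` ≈ 682 of that mass is
near-horizontal material (root hairs, young laterals) in the top
quadrant; `q3_vertical` is 0 because at 2.2 mm/day the primary root has
not yet reached the bottom quadrant of the 22 mm well.

Capacity and dilution arithmetic from the command line:

```bash
$ phytoscreen capacity
assays per plate: 80
platform capacity: 4320
$ phytoscreen dilution --stock-um 2500 --aliquot-ul 1.5
final concentration: 8.31 uM
solvent fraction: 0.33 %
```

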