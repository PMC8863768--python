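# synmorph

3D morphometry of B-cell nuclear grooves and immune-synapse organization,
with a synthetic confocal phantom generator that validates every measure
by parameter recovery.

## The problem

When a B cell meets an immobilized antigen — a 3 µm antigen-coated bead
or an antigen-coated coverslip — it builds an immune synapse: the
microtubule-organizing centre (MTOC) and lysosomes move to the contact
site and the lobed nucleus reorients so that its principal groove faces
the synapse. Quantifying this reorganization from multi-channel 3D
fluorescence stacks requires a battery of geometric measures that are
usually scattered across ad-hoc scripts. `synmorph` implements them as
one tested library for cell biologists analyzing confocal or
epifluorescence z-stacks of lymphocytes:

* **nuclear groove geometry** — orientation of the groove toward the
  bead (angle between the bead–cell axis $\vec{ab}$ and the
  cell–groove axis $\vec{bc}$, classified Polarized [0°, 45°] /
  Central (45°, 135°] / Antipolarized (135°, 180°]), orientation toward
  a coverslip synapse, lobe-baseline rotation, groove depth
  $h/d_\text{cell}$ (distance from the deepest groove point to the line
  between the two lobe apices, normalized to cell diameter) and groove
  area;
* **polarity indexes** — the MTOC or lysosome centre of mass projected
  onto the $\overrightarrow{\text{Cell}_{mc}\text{Bead}_{mc}}$ axis,
  giving a signed index in $[-1, +1]$;
* **lysosome organization** — fraction of LAMP1 intensity in the
  3.5 µm ring around the bead, inside/outside calls of the largest
  lysosome cluster relative to the perinuclear region, z-profiles from
  the synapse (ten 0.2 µm slices, normalized to sum to 100);
* **cytoskeleton–nucleus coupling** — nuclear/actin volumes by voxel
  counting and the lamin–actin overlap fraction with 1 px erosion and a
  2 px dilation tolerance;
* **function** — antigen-extraction percentages from OVA-bead time
  courses and surface-BCR levels on sum projections, plus radial Exo70
  profiles around the MTOC.

Because no public dataset accompanies these assays, the package ships a
**phantom generator**: analytic cells with a 3–4-lobed nucleus, a
carved principal groove, bead, MTOC, lysosomes and actin cortex,
rendered through a Gaussian PSF with Poisson and read noise — with every
ground-truth quantity known exactly, so the whole pipeline is validated
by simulate → analyze → recover.

## Worked example

```python
import synmorph as sm

# a polarized bead-conjugate phantom: MTOC at polarity 0.8, groove depth
# 0.2 facing the bead, 40% of lysosome intensity inside the 3.5 um ring
cfg = sm.desk_scale_config(rng_seed=42, mtoc_offset=0.8,
                           groove_depth_frac=0.2,
                           lysosome_inside_fraction=0.4)
scene = sm.make_scene(cfg)            # exact ground truth
stack = sm.render_stack(scene, cfg)   # PSF + noise rendering
rec = sm.analyze_cell(stack, cell_id="demo")

print(rec.groove_angle_deg)      # 0.48   (truth 0.0; groove faces the bead)
print(rec.orientation_category)  # Polarized
print(rec.groove_depth_norm)     # 0.177  (truth 0.200)
print(rec.mtoc_polarity_index)   # 0.799  (truth 0.800)
print(rec.lamp_ring_frac)        # 0.429  (truth 0.417)
print(rec.nucleus_volume_um3)    # 271.8  (truth 270.4)
print(rec.cluster_position)      # inside
```

The record carries every measure the stack supports; measures whose
inputs are missing stay `None` with a logged reason.
`sm.write_measurements(records, "cells.csv")` exports an analysis-ready
per-cell table (profiles go to a JSON sidecar); statistics are left to
your stats package of choice.

The same works from the shell:

```sh
synmorph simulate --config scene.yaml --out out/ --seed 7
synmorph analyze --stack out/scene.ome.tif --out cell.csv --mode bead
synmorph run --manifest manifest.yaml --config cfg.yaml --out results/
synmorph validate --seed 7 --n 20        # simulate -> analyze -> recover
```

`synmorph validate` renders seeded phantom grids (polarity offsets
−1…+1, orientations 0–180°, depths 0.1–0.3, ring fractions, extraction
time courses), runs the full pipeline on them and reports bias, RMSE
and maximum error per measure against the analytic truth, exiting
nonzero if any recovery tolerance is violated.

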