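# Methods

`synmorph` quantifies how B cells reorganize their lobed nucleus, the
microtubule-organizing centre (MTOC), lysosomes and cortical actin when
they form an immune synapse against an immobilized antigen — either a
3 µm antigen-coated bead or an antigen-coated coverslip. This note
documents the measurement definitions, the synthetic phantom model used
to validate them, the numerical choices, and the limits of what the
validation shows.

## Coordinate and data conventions

Stacks are held as `(channels, z, y, x)` arrays with voxel sizes
`(dz, dy, dx)` in µm; the physical position of voxel `(i, j, k)` is
`(i·dz, j·dy, k·dx)` relative to the stack corner. In coverslip
("dish") assays the synaptic plane is the low-z side. The default
confocal sampling is 0.2 µm optical sections with 0.07 µm pixels; an
epifluorescence mode with a 0.5 µm z-step is selectable. All measures
operate on physical coordinates, so anisotropic sampling is handled
throughout.

## Measurement definitions

**Groove orientation (bead assay).** With `a`, `b`, `c` the centres of
mass of bead, cell and principal nuclear groove, the orientation is the
angle between the vectors `a − b` and `c − b`, in [0°, 180°]. Cells are
classified Polarized on [0°, 45°], Central on (45°, 135°] and
Antipolarized on (135°, 180°]. The closed lower bin is a deliberate
convention so the Polarized supremum is exactly 45°.

**Groove orientation (dish assay).** The angle between `c − b` and the
foot-of-perpendicular vector from the cell centre to the synaptic plane;
0° means the groove faces the synapse.

**Groove detection.** The groove is found automatically as a convex-hull
deficit: per 2D section the deficit `hull(nucleus) − nucleus` is
computed, sections are linked into 3D components, and the principal
groove is the largest component (an optional direction hint or a manual
ROI overrides this, mirroring manual delineation). Sections whose
nucleus cross-section is below 30% of the maximal one are skipped: in
thin polar caps the lobes separate into islands whose inter-lobe gaps
are hull deficits but not grooves. The groove centre of mass is the
binary centroid of the region (a flag switches to lamin-intensity
weighting).

**Apices, baseline and depth.** In the section through the groove
centre, the hull edge that bridges the groove opening is identified (its
midpoint lies off the nucleus); its endpoints are refined toward the
true tangency points by taking the median position of the boundary
pixels within one pixel of the edge on either side of the opening —
on a pixelated circle the hull touches over a flat contact segment
centred on the tangency, so the median is a sub-pixel estimate. The
refined endpoints are the lobe apices, their segment the baseline. The
depth `h` is the largest distance from the baseline to a groove pixel,
reported normalized by the cell diameter, taken as the maximum Feret
diameter of the cell mask in the groove's section. Groove area is the
maximal per-section groove area in µm².

**Lobe rotation.** The angle between the apex baseline and the synaptic
plane, folded to [0°, 90°] (0° = baseline parallel to the plane, i.e. a
fully rotated groove); the raw baseline-to-plane-normal angle in
[0°, 180°] is stored alongside, since both conventions are in use.

**Polarity indexes.** The target (the MTOC point, or the
intensity-weighted LAMP1 centre of mass) is projected onto the axis from
the cell centre `Cellmc` to the bead centre `Beadmc`; the index is the
signed ratio of the projected distance to the cell–bead distance,
clamped to [−1, +1]: +1 fully polarized (target at the bead), 0 at the
cell centre, −1 anti-polarized. Clamping matters because segmented
centres can project slightly beyond the bead. Indexes are computed in
3D by default with a single-plane 2D mode available.

**Lysosome ring fraction.** LAMP1 intensity inside the sphere of radius
3.5 µm around the bead centre divided by total LAMP1 intensity. The
3.5 µm figure is interpreted as a radius: the bead radius is already
1.5 µm, so a 3.5 µm *diameter* region could not surround it. A 2D disc
mode at the bead's z-slice is available.

**Lamin–actin overlap.** Per z-slice, the segmented lamin mask is eroded
by 1 px to refine boundaries, the actin mask is dilated by a 2 px
tolerance to absorb diffraction-scale misregistration, and the fraction
is `|lamin ∩ actin| / |lamin|` with voxel counts pooled over slices (a
flag switches to averaging per-slice ratios). The tolerance is defined
strictly in pixels; the µm equivalent follows from the actual pixel size
(2 px at 70 nm ≈ 140 nm).

**z-profiles.** Mean fluorescence intensity (MFI) of LAMP1 or BCR within
the cell, in ten 0.2 µm slices starting at the synapse, each divided by
the total over the analyzed slices and multiplied by 100 — so the
profile sums to exactly 100 whenever signal exists. Normalizing over
the analyzed slices (rather than the whole stack) is a deliberate
choice; a flag provides whole-stack normalization.

**Lysosome cluster position.** The perinuclear region is a shell of
width 1 µm (configurable; the width is not standardized in the
literature) around the segmented nucleus. The largest LAMP1 component
is "inside" if it touches the nucleus or that shell at one or more
voxels — clusters only partially inside count as inside — otherwise
"outside".

**Radial Exo70 profile.** MFI over discs of growing radius (0–2 µm)
around a reference point (the MTOC), in the reference z-slice.

**Antigen extraction.** OVA fluorescence is summed over z (sum
projection) in a fixed disc around each bead; extraction at time *t* is
the percent intensity lost relative to *t* = 0, clamped to [0, 100].
The fixed-area radius defaults to 2.5 µm (bead radius + 1 µm) — the
area size is not standardized, so it is configurable. The projection's
median is subtracted first as a background estimate (the bead occupies a
small area, so the median is the camera floor); surface-BCR MFI uses
the same sum-projection machinery over a fixed area around the cell.

## Segmentation

Channels are thresholded with strict `>` comparisons by global Otsu
(default), a fixed threshold, a percentile, a half-max rule, a
noise-floor rule, or any user-supplied pixel classifier — the classifier
slot is a pluggable interface, with thresholds as the built-in options.
Otsu suits the volume-filling channels (nucleus, actin). For point-like
channels it fails structurally: when the foreground is a fraction of a
percent of the voxels, Otsu's threshold lands inside the background
distribution. The MTOC and bead therefore use `half_max`
(> 0.5 × channel max) and lysosomes use `noise_floor`
(> 6 × background σ, with σ estimated from the 84.13th intensity
percentile, which equals one σ for zero-clipped read noise when
foreground is sparse). Whole-channel intensity centroids are biased
toward the stack centre by background, so all point-structure centres
of mass are intensity-weighted *within* their segmentation mask.
Connected components use 6- or 26-connectivity with labels ordered by
decreasing voxel count (ties broken by centroid lexicographic order);
morphological operators run slice-wise in 2D with disk footprints by
default, matching per-slice processing conventions, with a 3D ball mode.

## The phantom model

The generator builds scenes with exact ground truth:

* **Cell**: a sphere, default radius 5 µm (primary-cell scale ≈ 3.25 µm
  is a parameter away), rendered as a cortical actin shell (0.4 µm)
  plus faint cytoplasm, and a BCR surface shell.
* **Nucleus**: a union of 3–4 lobe spheres (default radius 0.64 × cell
  radius) on a ring of radius 0.32 × cell radius, minus a
  parallel-sided slot that carves the principal groove. The slot opens
  along the configured groove direction; its half-width is set by the
  groove's angular half-width at the apex plane and its floor depth by
  `groove_depth_frac`. With this construction the groove centre of mass
  lies exactly on the configured direction (by symmetry), the apices are
  the analytic lobe tips, and normalized depth equals
  `groove_depth_frac` identically. A cone-shaped carve was rejected:
  its floor narrows below two PSF widths at the depths of interest,
  which no half-max segmentation can recover.
* **Bead**: a 1.5 µm-radius sphere tangent to the cell along the
  reference axis, with an OVA coat whose amplitude decays with the
  configured extraction fraction over a time course.
* **MTOC**: a Gaussian punctum (σ 0.25 µm) placed on the reference axis
  so its implied polarity index equals `mtoc_offset` exactly; Exo70 is
  a wider Gaussian (σ 0.6 µm) at the same point.
* **Lysosomes**: Gaussian puncta placed perinuclearly, packed near the
  synapse, or dispersed; a `lysosome_inside_fraction` puts an exact
  count fraction inside the 3.5 µm ring, with a 0.6 µm guard band so
  the configured fraction is crisp despite the PSF.

Rendering samples each structure on the voxel grid (every amplitude is
peak counts per structure voxel, default 500 — one realistic brightness
scale across channels; absolute fluorophore densities are free
parameters in reality), convolves with an anisotropic Gaussian PSF
(default σ = 0.35/0.13/0.13 µm in z/y/x), applies Poisson shot noise and
additive Gaussian read noise (σ = 2 counts), and clips at zero.
Everything is seeded: identical configurations give bit-identical
stacks.

**What the phantom does not emulate**: non-spherical cells, chromatin
texture, uneven lamin staining, spherical aberration and depth-dependent
PSFs, bleaching, cell motility, touching cells, and the irregular lobe
shapes of real B-cell nuclei. Passing recovery tests therefore shows
the measures are correct *given* adequate segmentation, not that
segmentation is adequate on arbitrary real data — on real stacks the
manual-ROI override and the pluggable classifier exist precisely for the
cases automatic thresholds miss.

## Validation sizes and tolerances

The self-validation loop (`synmorph validate`, also the recovery test)
renders phantoms at (0.2, 0.15, 0.15) µm voxels — coarser than the
confocal default, chosen so a full seeded grid (20 phantoms per setting)
runs in minutes while keeping ≥ 13 voxels across the cell radius; noise
and amplitudes stay at defaults. Recovery tolerances: polarity index
±0.05 across offsets {−1, −0.5, 0, 0.5, 1}; groove orientation ±2°
across {0°, 30°, 60°, 90°, 135°, 180°}; normalized depth ±0.03 across
{0.1, 0.2, 0.3}; ring fraction ±0.05; extraction percentages ±2 for
true values {0, 25, 60}%. Typical observed errors are well inside
these: the depth estimate carries a small negative bias (≈ −0.02 at
depth 0.2) because segmentation erodes high-curvature lobe tips and the
PSF rounds the slot floor; both effects shrink `h`.

Degenerate inputs are defined rather than crashed on: empty
segmentations warn and yield missing values; a convex nucleus raises a
"no groove found" error; zero-length axes raise degenerate-geometry
errors; an empty record list writes a header-only table.

## Known limitations

* Groove detection assumes the principal groove is the largest hull
  deficit; heavily fragmented nuclei may need the direction hint or a
  manual ROI.
* Apex extraction works in a single 2D section; grooves that twist
  along their length are summarized by the section through their centre.
* The trainable pixel-classifier pre-filter used in the original
  workflow is out of scope; the pluggable classifier interface accepts
  one, but none is shipped.
* Group-comparison statistics are deliberately excluded: the pipeline
  exports per-cell tables for any statistics package.
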