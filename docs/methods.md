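# Methods

## Scope and model

`marrowquant` segments a user-annotated region of an H&E-stained
brightfield section into five mutually exclusive compartments — bone,
hematopoietic (nucleated) cells, adipocyte ghosts, interstitium/
microvasculature, and an unattributed remainder — and derives the standard
marrow histomorphometry outputs from the resulting label map. The central
modeling assumptions are:

- **Beer–Lambert stain mixing.** Absorbance is linear in optical density,
  `OD_c = log10(white_c / I_c)` per channel, and hematoxylin/eosin
  contributions add linearly in OD space. The white reference is the
  per-channel *median* intensity of the user's background annotation
  (median for robustness to dust); background correction is division
  before the log, so background pixels sit at OD 0. Stain vectors default
  to the standard published H&E OD triplets (hematoxylin ≈ (0.65, 0.70,
  0.29), eosin ≈ (0.07, 0.99, 0.11), residual = their normalized cross
  product) and are user-overridable; automatic vector estimation is out of
  scope.
- **Priority composition.** Masks are composed in the fixed order
  BONE > HEMATO > ADIPO > INTERSTITIUM > UNDETECTED. Every pixel outside
  the analysis region (tissue ∖ artifacts) — including the bone dilation
  ring — is EXCLUDED, and the four marrow labels always partition Ma.Ar
  exactly, which makes the area identity `Ma.Ar = H + A + I + U` a
  verifiable invariant rather than an approximation.
- **Ghosts are voids.** A delipidated adipocyte is detected by its
  near-background interior, and individuality is restored by a
  marker-controlled watershed whose flooding surface is the inverted
  Euclidean distance transform plus the smoothed eosin signal (weight
  4 μm per OD unit), so fragmentation lines prefer stained membranes.

Both cellularity conventions are reported side by side: Eq. 1
`H/(H+A)` (the pathologists' ratio, undefined when `H+A = 0`) and Eq. 2
`100·H/Ma.Ar` (the compartment percentage, undefined when `Ma.Ar = 0`).
Undefined ratios propagate as NA, never as zero. Percent bone is reported
against the tissue ROI and is user-interpretable: it means trabecular bone
when the boundaries trace the marrow cavity and cortical+trabecular bone
when they enclose the cortex.

## Tunable parameters

| parameter | default (marrow / adipo) | units | role |
| --- | --- | --- | --- |
| `min_adipocyte_area` | 120 / 300 | μm² | retention window, inclusive |
| `max_adipocyte_area` | 5000 / 2500 | μm² | retention window, inclusive |
| `min_circularity` | 0.3 / 0.0 | – | 4πA/P² floor, inclusive |
| `exclude_edges` | false / true | – | drop ghosts touching border/excluded |
| `bin_width` | 250 | μm² | size-histogram bin |
| `pixel_size` | unset | μm/px | from TIFF tags or user; required |
| `bone_dilation_radius` | 2.0 | μm | endosteal suppression ring |
| `smoothing_sigma` | 1.0 | μm | Gaussian smoothing of stain maps |
| `min_bone_object_area` | 500 | μm² | smallest bone object kept |
| `threshold_method` | otsu | – | `otsu` or `fixed` (user OD values) |

The adipocyte filters and the 250 μm² bin are the recommended published
presets per mode; the operator parameters below the line are this
package's documented defaults — the smoothing scale is sub-nuclear, the
2 μm ring matches one endosteal cell layer, and 500 μm² is safely above
stain debris but below any real trabecular profile. All lengths live in
physical units and are converted to pixels only inside the operators
(structuring radii round to the nearest integer ≥ 1 px; a zero radius
disables the operation).

## Numerical choices

- **Thresholds are computed within the region they apply to** (analysis
  region for bone, Ma.Ar for nuclei, Ma ∖ hemato for voids), so empty
  slide background cannot skew them. A channel whose OD spread is below
  0.05 is treated as degenerate: thresholding is skipped with a warning
  (empty mask), except for the void test where the region mean decides —
  an all-void region is all candidates, an all-stained one has none.
- **Void cap.** Ghost "void" pixels are near background by definition.
  When the marrow carries several stained populations (serous wash,
  membranes, RBCs), Otsu on total OD can split *between stained modes*
  and admit visibly stained pixels as void; the void threshold is
  therefore capped at 0.12 OD, just above the 0.08 OD interstitium floor.
- **Bone texture criterion.** Bone matrix and RBC lakes are both
  eosin-bright; only bone is texturally flat at nuclear scale. Bone pixels
  must have local eosin std ≤ 0.06 OD in a 5 μm window. The criterion is
  undefined across the matrix boundary, so after size filtering the mask
  is re-grown by 4 μm into pixels that pass the intensity tests. Hole
  filling is area-limited (≤ 4× `min_bone_object_area`): a cortical ring
  must not have its entire cavity "filled" as porosity.
- **Watershed seeding.** Seeds are h-maxima of the distance transform with
  depth 1.5 μm, which suppresses over-seeding of slightly lumpy ghosts;
  candidate components too shallow to seed keep their own label, so the
  watershed output always partitions the candidate mask. Everything is
  deterministic; reruns are byte-identical.
- **Perimeter and circularity.** Circularity is 4πA/P² clamped to [0, 1].
  The perimeter is the length of the marching-squares contour of the
  lightly smoothed mask — accurate for compact shapes (digitized disks
  score ≥ 0.99, axis-aligned squares land within 0.05 of π/4) — with the
  4-direction Crofton estimate as a lower-bound guard for sub-resolution
  shapes whose smoothed contour vanishes (1-px lines score ≈ 0.07). Pure
  Crofton was rejected because it biases axis-aligned squares to ≈ 0.88.
- **Rejected candidates.** Ghost fragments that fail the filters revert to
  interstitium if they pass the eosin floor, otherwise to undetected; this
  fate falls out of the pipeline order rather than special-casing.
- **Filter order.** The recorded rejection reason is the first failure in
  the order size-low, size-high, circularity, edge; bounds are inclusive.
  The edge test counts contact with excluded regions (artifacts, the bone
  ring) as well as the image frame.

One caveat documented as behavior: enlarging the artifact set shrinks the
detected compartments but can *grow* the unattributed remainder by a few
pixels — an artifact that clips a ghost makes the fragment fail the
per-object filters, and adaptive thresholds shift slightly with the
region. Monotonicity is therefore asserted (and holds) for the four
detected compartments only.

## Synthetic study material

The generator forward-renders stain concentration maps through the same
Beer–Lambert model the analysis inverts (`I = white·10^(−M·c)`, rounded to
8 bit, plus additive Gaussian intensity noise, sd 3/255 by default) and
returns pixel-level truth labels, a per-ghost truth table and the matching
annotations. It emulates:

- a cortical ring (22 μm) and trabecular ellipses, eosin-dense
  (OD 0.75) and texturally flat;
- adipocyte ghosts: white interiors with 1.5 μm eosin membranes
  (OD 0.5), lognormal radii around 13 μm, a rim nucleus with
  probability 0.5 (truth-labeled hematopoietic — the documented
  adipocyte-nucleus bias), interspersed through the section as in real
  marrow; adjacent ghosts may share membrane walls;
- a nucleated territory: near-confluent 3 μm hematoxylin nuclei
  (OD 0.9, spacing 6 μm) on a pale cytoplasm wash, occupying the top
  rows of whatever space the ghosts leave; slivers too narrow to hold a
  nucleus are opened away and belong to the interstitium;
- interstitium: serous wash (eosin OD 0.2) plus speckled RBC lakes
  (discoid cores OD 0.65 on plasma 0.3) that exercise the bone texture
  veto;
- undetected area: thin white strips in a compact band; the first strip
  doubles as the Background annotation (an honestly empty region inside
  the tissue boundary).

Compartment fraction targets are met by construction — ghosts are placed
on minimally spaced hex lattices (descending radii at high packing, then
greedy maximal-disk gap fill), the nucleated territory is cut row-wise
from what remains — and enforced by rejection resampling with a ±3-point
tolerance; irreconcilable targets raise an error. Dense sections
(> ~45% packing) use larger first-pass ghosts and a single trabecula,
mirroring the hypertrophy and sparse trabecularization of distal
yellow-marrow sites. The adipose sheet is a jittered-grid Voronoi tiling
with shared membrane walls, sparse stromal nuclei and a stroma margin;
`membrane_gap_fraction` opens the central ~40% of that fraction of walls
(at most one per cell — junction blow-outs would pool several cells into
a single watershed basin, which is not the pairwise hypo-fragmentation
scenario being modeled).

What the generator does **not** emulate: stain gradients across a slide,
out-of-focus regions, sectioning chatter, megakaryocytes and other large
cytoplasm-rich cells, lobulated or collapsed ghosts, genuine vascular
anatomy. Passing the recovery tests therefore demonstrates that the
pipeline inverts its own image-formation model faithfully across the full
red-to-yellow composition range — not that it matches pathologists on
real slides, which requires scanner data outside this package.

## Validation protocol and problem sizes

The test suite and `scripts/acceptance.py` run, at 1 μm/px:

- a 20-section sweep (384×384 px) of truth adiposity 0–60% of Ma.Ar with
  reciprocal hematopoietic content (Eq. 1 cellularity spans ~0–100%);
  measured-vs-truth fractions are fit by least squares; observed
  R² > 0.999 and slopes within 1.00–1.03 for both compartments;
- per-compartment IoU on noise-free renders (bone ≈ 0.98, hematopoietic
  ≈ 0.96, adipocyte ≈ 0.99);
- a 200-ghost adipose sheet (512×512 px): retained count within ±1–3%,
  mean per-ghost area error ≈ 1%, 250 μm²-binned histogram
  total-variation distance ≈ 0.03–0.07, and ≤ ~1% change in total
  adipocyte area under membrane erasure;
- the stain render→unmix round trip on random concentration fields in
  the physiological range (≤ 0.6 OD per stain), max error ≈ 0.011 OD
  against the 8-bit quantization bound of 0.02.

These sizes keep the full suite under a minute while leaving every
operator's working regime (dense packing, empty compartments, degenerate
channels) exercised.

## Known limitations

- Interstitium and microvasculature are a single compartment; separating
  them would need vascular segmentation.
- Outputs are whole-ROI aggregates; regional gradients within one bone
  require the user to split the image.
- Megakaryocyte-like objects (eosin-dense, texture-flat) are classified
  as bone and hence subtracted from Ma.Ar — documented behavior, tested.
- Endosteal nuclei inside the 2 μm dilation ring are excluded from the
  hematopoietic mask; detached bone-lining cells elsewhere are not.
- The human-trephine setting (duller stains, no cortical enclosure) needs
  different thresholds; only the `fixed` threshold mode is offered as an
  escape hatch.
- Pyramidal/tiled whole-slide formats are out of scope; export flat TIFF.
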