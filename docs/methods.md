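# Methods

## Scope and data model

`neuritequant` quantifies four fluorescence-microscopy readouts of neurite
degeneration — integrity/fragmentation indices, mitochondrial count density
and shape classes, annexin-V colocalization and integrated intensity, and
2D monolayer viability/neurite area — and aggregates them over the
replicate structure of a high-content experiment.  The unit of analysis is
the `ImageField`: one 2D intensity grid for one channel of one microscope
field, carrying the pixel calibration (µm/px).  Every physical area is
`pixel count × pixel_size²`; no other calibration enters anywhere.

## Preprocessing chain

The mitochondria channel (and, by default, every other channel — each
stage can be disabled) is processed as:

1. **Background subtraction**, radius 50 px.  The background estimate is a
   grayscale morphological opening with a disk footprint, subtracted and
   clipped at zero.  This variant is fully specified and monotone — the
   opening never exceeds the image, so the operator never brightens a
   pixel, and constant images map to zero.  The footprint defaults to
   scikit-image's `decomposition="sequence"` disk approximation, which is
   ~20× faster than the exact disk on a ~900² field with visually
   indistinguishable output; `footprint_decomposition=None` selects the
   exact disk.
2. **Unsharp mask**, weight 0.6, radius 2 px, in the normalized
   subtractive form `(img − w·G_σ(img)) / (1 − w)` with the radius
   interpreted as the Gaussian σ in pixels, clipped to the bit-depth
   range.  A uniform image is a fixed point and `w → 0` is the identity.
3. **Median filter**, radius 1 px = the full 3×3 neighborhood (corners
   included); larger radii use a Euclidean disk.

## Segmentation

* **Otsu threshold** over 256 equal-width bins spanning the observed
  intensity range (for 8- and 16-bit input alike), maximizing the
  between-class variance; ties break toward the lowest qualifying bin
  boundary.  Binarization is the strict comparison `pixels > threshold`.
  A constant image has no threshold and raises.
* **Signal-free-channel guard.**  Otsu always returns a threshold, even on
  a channel containing nothing but noise (where it just bisects the noise
  distribution).  The pipeline therefore computes the class separation
  `(μ_fg − μ_bg)/σ_bg` at the chosen threshold and declares the channel
  empty below 4.0 (configurable).  Splitting a unimodal noise
  distribution yields separations around 1.5–3; genuine staining in these
  assays yields 50–500.  This matters for, e.g., the TMRE channel of a
  fully depolarized culture, which must count zero mitochondria rather
  than segmenting noise.
* **Watershed separation** of touching objects on the Euclidean distance
  transform.  Markers are the regional maxima of the distance map after
  two suppressions: maxima with distance < 1 px are discarded, and the
  map is quantized (`floor(dist/2)`) before maxima extraction so that the
  ±1 px ridge wiggles of a digital ellipse collapse into a single plateau
  marker.  Remaining maxima closer than 2 px are merged.  Consequences:
  convex blobs — including long ellipses — keep one label; touching blobs
  whose neck is more than ~2 px shallower than their peaks split along
  the neck; components whose maxima were all suppressed (thin lines)
  receive one rescue marker at their distance argmax, so no object is
  lost.  Watershed lines are removed from the mask.  Connectivity is
  8-connected throughout, for components and labels.
* **Particle measurement.**  One row per object with area strictly
  greater than 1 µm² (strict inequality; an object of exactly 1 µm² is
  excluded).  The fitted ellipse comes from the second-order central
  moments of the mask (axis = 4·√eigenvalue); AR = major/minor with both
  axes floored at one pixel width so single-pixel objects report AR = 1
  instead of dividing by zero.

The neurite (calcein) channel is *not* watershed-separated — the
degeneration indices count connected components of the binarized field —
while mitochondria and nuclei channels are.  Which channels get the
watershed is a config list.

## Readouts

* **Integrity** = 100 · mean object area / intact-control mean area;
  **fragmentation** = 100 · object count / degenerated-control count.
  "Average size" is the arithmetic mean.  Anchors are computed per
  biological replicate from that replicate's own control fields, then the
  normalized per-field values are averaged fields → technical →
  biological.
* **Mitochondrial density** = retained TMRE⁺ object count / calcein⁺ area
  (µm²); an empty neurite mask marks a failed field and raises.  Reported
  raw and as % of the intact control.
* **Shape fractions** over retained objects with the strict AR rules
  (boundary values 1.5 and 3.0 are intermediate).  A validity flag
  requires more than 100 evaluated mitochondria from at least 5 fields,
  the morphometry sampling rule.
* **Manders M1/M2** with per-channel thresholds (Otsu by default, manual
  override available): M1 = Σ A over pixels above threshold in both
  channels / Σ A over A-positive pixels; M2 symmetric.  Costes automatic
  thresholding is out of scope.
* **Integrated intensity** = Σ over the object mask − (mean of one
  unspecific-background region) × mask size, floored at 0 — the same
  formula for annexin-V fields and densitometry.  In the batch pipeline
  the background region is the complement of the 5-px-dilated signal
  mask.
* **Monolayer viability.**  Nuclei are Otsu+watershed segmented (minimum
  nucleus area 20 µm²), expanded by 3.2 µm into non-overlapping soma
  regions (`expand_labels`).  A cell is double-positive when ≥ 30% of its
  soma-region pixels exceed the calcein threshold; the 30% fraction is a
  package choice (the per-cell rule of the original instrument software
  is not public) and is configurable.  Neurite area is the calcein⁺ area
  outside all somata.

## The simulator

The generators define the study conditions the tests run under; their
defaults are fixed once:

* **Geometry.**  Square fields of 0.32 mm² at 0.65 µm/px (≈870² px),
  matching 10×-class sampling, 16-bit, signal amplitude 8000 counts over
  a 200-count offset.  Mitochondrial morphometry was acquired with a
  63×/1.4 oil objective, which the mito-oriented configurations represent
  as 0.1 µm/px over ~0.02 mm² fields.  The pixel size is never stated by
  typical acquisition metadata-free exports, so it is an explicit config
  value surfaced in all outputs.
* **Neurites** are smooth, locally directional random curves (mean-
  reverting heading with a turn clamp — curves meander but cannot double
  back onto themselves), 1.5 µm wide, either entering from field edges
  ("radial", emulating the spheroid corona) or confined to horizontal
  bands ("bands").  The banded layout guarantees inter-neurite
  separation and exists so that exact-count tests can use fields
  *certified* non-touching; certification is computed, not assumed: the
  generator relabels its own noise-free mask and flags the field only if
  the component count equals the object count.
* **Fragmentation model.**  Breakpoints arrive as a Poisson process along
  each curve with mean `d · L / ℓ₀` (ℓ₀ = 20 µm), removing a fixed 2 µm
  gap (measured edge-to-edge between the rendered fragment masks, with a
  one-pixel guard against grid rounding).  Half of the fragments (by
  default) convert to near-circular blebs with area-preserving radius
  capped at 1.5× the neurite width — beads, not giant disks.  This is the
  simplest generative process with the right monotone behavior: expected
  object count increases and expected fragment size decreases in *d*.
* **Mitochondria** are filled ellipses along the surviving fragment
  center lines: arc positions Poisson at 12 per 100 µm, thinned to a
  2 µm minimum arc spacing (mitochondria are solid organelles and cannot
  interpenetrate; the hard-core process also keeps them individually
  resolvable, as in the real morphometry), lateral jitter of width/4,
  orientation along the local tangent.  Minor axis 1.0 µm ± 15%; aspect
  ratios from a configurable distribution (default log-normal,
  median ≈ 2.7, ~5% round / ~40% elongated — a healthy-culture profile).
  Each record carries the true center, axes, AR, the shape class under
  the same classification rule the metrics use, and a Bernoulli
  polarized flag; only polarized mitochondria render in the TMRE channel,
  all render in the cytochrome-c channel.
* **Monolayer** fields place non-overlapping cells (rejection sampling
  with a hard minimum separation), nucleus radius 5 µm; a viable fraction
  (Bernoulli, or exact assignment if configured) additionally gets a
  calcein⁺ soma (nucleus + 3.5 µm, deliberately larger than the 3.2 µm
  analysis expansion so viable somata are unambiguously calcein-filled)
  and 3 neurites of ~60 µm.  Ground truth includes the noise-free calcein
  area outside the 3.2 µm-expanded true nuclei — the same definition the
  scorer uses.
* **Noise model**: per-object brightness jitter (±15%), a planar
  illumination gradient of random orientation (80 counts), Poisson photon
  noise, Gaussian read noise (σ = 15), quantization to the bit depth.
  This is the minimum that makes background subtraction and Otsu
  non-trivial.  `NoiseConfig.off()` renders noise-free for ground-truth-
  exact tests.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: no optical PSF (objects have sharp edges, so
segmentation here is easier than on real micrographs), no out-of-focus
light or 3D structure, no bleaching or time-lapse drift, no autofluorescence
texture, no debris or non-neuronal objects.  Recovery numbers on synthetic
fields are best-case; the pipeline's operator parameters, not its measured
accuracies, are what transfer to real images.

## Replicate aggregation

Averaging order is fixed: fields → technical-replicate mean →
biological-replicate mean → condition mean ± SD/SEM (SD with ddof = 1,
reported missing for n = 1).  Permuting fields within a technical
replicate cannot change the result.  Technical replicates with fewer than
3 usable fields (configurable) are excluded and reported; a condition left
with no surviving fields is an error, not a silent gap.  Normalization to
controls happens at the anchor level (per biological replicate) *before*
averaging.  Both SD and SEM are emitted, since figures use either.

## Numerical and design choices

* Thresholding and the 1 µm² filter use strict `>`.
* Otsu ties break to the lowest boundary; the threshold returned is a bin
  edge, so for full-range 8-bit images no pixel ever sits exactly on it.
* The degeneration-index binarization uses Otsu by default (with a
  manual-threshold override) — the acquisition protocol only states that
  images "were binarized".
* Per-field seeds in batch simulation derive from the experiment seed via
  `SeedSequence([seed, condition, bio, tech, field])`, so any subset of an
  experiment is reproducible in isolation.
* CSV outputs are sorted on stable keys; identical config + inputs give
  byte-identical files.

## Problem sizes in tests

The acceptance-style tests run at the study's field geometry (0.32 mm² at
0.65 µm/px for degeneration; ~0.02 mm² at 0.1 µm/px for morphometry) with
10 fields per degeneration level, ≥500 ellipses for shape recovery, 5
fields per polarization level, 200-nuclei monolayers, and a
3-condition × 3-biological × 5-technical × 10-field determinism run at
512² px.  `scripts/acceptance.py` measures the same quantities at reduced
field counts (4 per degeneration level, ~200 ellipses, 2 fields per
polarization level, a 2-condition determinism run) — sizes chosen so a
complete from-scratch rerun stays cheap while every estimate keeps enough
objects (hundreds) to be stable.

## Known limitations

* The watershed quantization (2 px) under-splits deeply overlapping
  mitochondria whose neck is nearly as wide as the objects; at the default
  hard-core spacing this costs a few percent of counts, and cancels almost
  entirely in the TMRE/cytochrome-c density *ratio*.
* Mander's coefficients use global per-channel thresholds; no
  Costes-style automatic threshold search.
* The particle-table ellipse fit assumes roughly convex objects; for long
  curved fragments AR under-reports the true elongation (moments measure
  the bounding ellipse of the curve, not its arc length).
* Morphological background subtraction under-corrects within one
  structuring radius of the field border (the opening cannot see past the
  edge); metrics are unaffected because all comparisons share the bias.
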