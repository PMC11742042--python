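# neuritequant

Quantification of neurite degeneration from fluorescence micrographs —
with a ground-truth-emitting synthetic microscopy simulator, so the whole
pipeline is testable without any raw image data.

## The problem

After axotomy, isolated neurites of cultured human neurons (e.g. LUHMES
2.5D spheroid cultures) execute a programmed degeneration: the calcein-
stained neurite network fragments into blebs, mitochondria lose membrane
potential and round up, and phosphatidylserine appears on the surface
(annexin-V staining).  High-content screens read all of this out from
multi-channel epifluorescence fields.  `neuritequant` implements the image
quantification for these readouts:

* **Neurite integrity / fragmentation.**  Fields are binarized and
  objects counted and sized.  Integrity is the mean object area as a
  percentage of an intact (uncut or freshly isolated) control; the
  fragmentation index is the object count as a percentage of a completely
  degenerated control:

  `integrity = 100 · Ā_field / Ā_intact` , `fragmentation = 100 · N_field / N_degenerated`

* **Mitochondrial morphometry.**  The mitochondria channel is background-
  corrected (morphological opening, radius 50 px), unsharp-masked
  (weight 0.6, radius 2 px), median-filtered (radius 1 px), Otsu-
  thresholded, watershed-separated, and objects > 1 µm² are measured.
  Counts are normalized to the calcein⁺ neurite-covered area.  The
  fitted-ellipse aspect ratio AR = major/minor (4·√eigenvalues of the
  second-order central moments) classifies shapes: AR < 1.5 *round*,
  AR > 3 *elongated*, otherwise *intermediate*.

* **Thresholded Manders colocalization** M1/M2 between annexin-V and
  calcein (1 = total colocalization, 0 = none), plus background-corrected
  integrated intensity (densitometry-style, single background region).

* **2D monolayer viability.**  Nuclei (H-33342) are segmented and expanded
  by 3.2 µm into somata; viability is the calcein/H-33342 double-positive
  ratio and neurite area is the calcein⁺ area outside all somata, both
  normalized to untreated controls.

* **Replicate aggregation** mirroring the experiment design: ten fields
  per condition, 3–5 technical replicates, biological replicates as means
  of technical replicates, summary tables with SD and SEM.

The simulator (`simulate_neurite_field`, `simulate_mitochondria`,
`simulate_monolayer_field`) renders all of these scenes with a Poisson
breakage model for fragmentation, elliptical mitochondria with
configurable aspect-ratio distributions and polarization status, and a
realistic noise model (illumination gradient, Poisson photon noise,
Gaussian read noise) — and emits the exact noise-free object inventory for
every field.

## A worked example

```sh
python examples/degeneration_timecourse.py
```

```
  time  objects  mean area (µm²)  integrity %  fragmentation %
   0 h        1          30705.5        100.0              0.2
   6 h      226             72.4          0.2             43.9
  12 h      356             47.8          0.2             69.2
  18 h      514             31.4          0.1            100.0
```

At 0 h the corona is essentially one connected calcein⁺ object per field
(~31,000 µm²).  As the simulated degeneration level rises, the field
shatters into hundreds of small fragments: integrity (mean object size,
% of intact) collapses, while the fragmentation index (object count, % of
the fully degenerated control) climbs to 100%.

Other examples: `mitochondria_morphometry.py` (count density and shape
classes), `annexin_colocalization.py` (Manders M1/M2), 
`monolayer_viability.py` (2D viability + neurite area), and
`full_experiment.py` (the batch pipeline end to end).

## Command line

```sh
neuritequant simulate --config experiment.json --out dataset/
neuritequant quantify --images dataset/ --out results/ --pixel-size 0.65
neuritequant aggregate --field-metrics results/field_metrics.csv \
    --manifest dataset/manifest.json --out summaries/
neuritequant report --summary results/condition_summary.csv \
    --manifest dataset/manifest.json --out timecourse.svg
```

`quantify` writes particle tables, per-field metrics, technical/biological/
condition summaries, a QC table of flagged fields, the resolved
configuration, and a log; reruns are byte-identical.

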