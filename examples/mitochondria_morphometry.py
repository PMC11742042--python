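"""Count and classify mitochondria along simulated neurites.

Renders a TMRE/cytochrome-c pair at 63×-like sampling (0.1 µm/px), runs the
full preprocessing chain (background subtraction, unsharp mask, median
filter), Otsu thresholding and watershed separation, and prints the count
density per neurite area and the round/intermediate/elongated fractions
from the fitted-ellipse aspect ratios.
"""

import neuritequant as nq

cfg = nq.SimConfig(
    seed=7,
    pixel_size_um=0.1,          # high-NA oil objective sampling
    field_area_um2=20_000,
    n_neurites=6,
    layout="bands",
    polarized_fraction=0.8,     # 80% of mitochondria hold a membrane potential
)

channels, gt = nq.simulate_neurite_field(cfg)
mito_channels, records = nq.simulate_mitochondria(cfg, gt.skeletons)

neurite_mask, _, _ = nq.segment_field(channels["calcein"], "calcein")
_, _, tmre = nq.segment_field(mito_channels["tmre"], "tmre")
_, _, cytc = nq.segment_field(mito_channels["cytc"], "cytc")

density = nq.mito_density(tmre, neurite_mask, cfg.pixel_size_um)
stats = nq.classify_shapes(cytc, n_fields=1)

print(f"simulated mitochondria:        {len(records)}")
print(f"TMRE+ (polarized) objects:     {len(tmre)}")
print(f"cytochrome-c objects:          {len(cytc)}")
print(f"TMRE density:                  {density * 1e3:.2f} objects per 1000 µm² of neurite")
print(f"recovered polarized fraction:  {len(tmre) / len(cytc):.2f} "
      f"(simulated {cfg.polarized_fraction})")
print(f"shape fractions (r/i/e):       {stats.fraction_round:.2f} / "
      f"{stats.fraction_intermediate:.2f} / {stats.fraction_elongated:.2f}")
print(f"sampling valid (>100 from ≥5 fields): {stats.valid}")
print(
    "\nOnly polarized mitochondria take up TMRE, so the TMRE/cytochrome-c"
    "\ncount ratio reads out the polarized fraction; aspect ratios < 1.5"
    "\ncount as round, > 3 as elongated."
)
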