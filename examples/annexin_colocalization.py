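"""Quantify annexin-V exposure on degenerating neurites.

Simulates a field where a fraction of calcein-positive fragments expose
phosphatidylserine (annexin-V signal), then computes the background-
corrected integrated annexin intensity and the thresholded Manders
colocalization coefficients against the calcein channel.
"""

from skimage import morphology

import neuritequant as nq

cfg = nq.SimConfig(seed=12, degeneration=0.6, annexin_positive_fraction=0.7)
channels, gt = nq.simulate_neurite_field(cfg)

annexin = channels["annexin"]
annexin_mask, _, _ = nq.segment_field(annexin, "annexin")
background = ~morphology.dilation(annexin_mask, morphology.disk(5))

signal = nq.integrated_intensity(annexin, annexin_mask, background)
coloc = nq.manders(annexin, channels["calcein"])  # per-channel Otsu thresholds

print(f"annexin-V integrated intensity (bg-corrected): {signal:.3e}")
print(f"Manders M1 (annexin in calcein+ pixels):       {coloc.m1:.3f}")
print(f"Manders M2 (calcein in annexin+ pixels):       {coloc.m2:.3f}")
print(f"simulated colocalizing fraction:               {gt.true_coloc_fraction:.3f}")
print(
    "\nM1 near 1 shows annexin signal sits almost entirely on calcein+"
    "\nstructures (membrane-intact fragments exposing phosphatidylserine);"
    "\nM2 tracks the fraction of the neurite mass that is annexin-positive."
)
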