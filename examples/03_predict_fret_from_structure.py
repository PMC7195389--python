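"""Predict an smFRET efficiency distribution from a structure.

Computes dye accessible volumes (AVs) at two labelling sites on a toy
structure — every clash-free position a dye on a 20 Å linker can reach — and
converts sampled inter-dye distances to FRET efficiencies with R0 = 60 Å
(the Alexa 488/594 pair).
"""

import numpy as np

from interdom.avfret import (
    DyeParameters,
    accessible_volume,
    forster_distance_at,
    predict_efret_distribution,
)
from interdom.synthetic import make_toy_multidomain

gt = make_toy_multidomain(seed=1)
dye = DyeParameters(r0=60.0)

site_a, site_b = 20, 110  # one site per distal domain
av_a = accessible_volume(gt.structure, site_a, dye)
av_b = accessible_volume(gt.structure, site_b, dye)
print(f"AV at residue {site_a}: {len(av_a)} allowed dye positions")
print(f"AV at residue {site_b}: {len(av_b)} allowed dye positions")

mean_dist = float(np.linalg.norm(av_a.mean_position - av_b.mean_position))
print(f"mean inter-dye distance: {mean_dist:.1f} Å")
print(f"distance at E = 0.5 for this pair: {forster_distance_at(0.5, dye.r0):.1f} Å")

dist = predict_efret_distribution(av_a, av_b, r0=dye.r0, n_samples=20000, seed=0)
for mean, sd, weight in dist.components:
    print(f"fitted component: E = {mean:.3f} ± {sd:.3f} (weight {weight:.2f})")

print(
    "\nBecause the mean dye separation is well below R0 = 60 Å, the predicted "
    "distribution sits at high E; dye-linker flexibility broadens it. "
    "Comparing such predictions with measured burst histograms tests whether "
    "a crystal-structure arrangement persists in solution."
)
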