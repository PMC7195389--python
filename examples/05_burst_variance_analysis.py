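"""Burst variance analysis (BVA): detect sub-millisecond dynamics.

Within each burst, E is recomputed in consecutive windows of 5
donor-excitation photons. For a static molecule the spread across windows is
pure binomial shot noise, sqrt(E(1−E)/5); conformational exchange faster than
the burst duration adds variance on top.
"""

from interdom.bursts import PhotonStream, bva, search_bursts
from interdom.synthetic import Population, StreamConfig, simulate_photon_stream

LOW_BG = {"dd": 50.0, "ad": 50.0, "aa": 80.0, "da": 20.0}

static = StreamConfig(populations=[Population(E=0.4)], burst_rate=15.0, background=LOW_BG)
dynamic = StreamConfig(
    populations=[Population(E=0.2, E2=0.6, k12=10000.0, k21=10000.0)],
    burst_rate=15.0, background=LOW_BG,
)

for name, cfg in (("static E=0.4", static), ("two-state 0.2↔0.6, ~10 switches/burst", dynamic)):
    d, _ = simulate_photon_stream(cfg, duration=60.0, seed=2)
    result = bva(search_bursts(PhotonStream.from_dict(d)), window=5)
    print(f"\n{name}:")
    print("  E_bin   mean sd   shot-noise sd   n bursts")
    for _, row in result.bins[result.bins["n"] >= 30].iterrows():
        print(f"  {row['e_mean']:.2f}    {row['sd_mean']:.3f}     {row['sd_shot']:.3f}"
              f"          {int(row['n'])}")

print(
    "\nStatic bursts sit on the shot-noise arc; the switching population "
    "lies clearly above it — the smFRET signature of inter-domain motion "
    "faster than the ~1 ms diffusion transit."
)
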