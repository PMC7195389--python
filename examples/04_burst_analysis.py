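"""Full ALEX burst pipeline: search, correct, filter, fit.

Simulates a photon stream with two FRET populations (E = 0.2 and 0.6) plus
donor-only and acceptor-only species under known correction factors
(α = δ = 0.05, γ = 0.8, β = 1.2), then recovers everything from the photons
alone.
"""

from interdom.bursts import (
    PhotonStream,
    correct_bursts,
    estimate_factors,
    filter_bursts,
    fit_efret_distribution,
    search_bursts,
)
from interdom.synthetic import Population, StreamConfig, simulate_photon_stream

config = StreamConfig(
    populations=[
        Population(E=0.2, S=0.5, weight=0.35),
        Population(E=0.6, S=0.5, weight=0.35),
        Population(E=0.0, S=1.0, weight=0.15),  # donor-only
        Population(E=0.0, S=0.0, weight=0.15),  # acceptor-only
    ],
    burst_rate=15.0, alpha=0.05, delta=0.05, gamma=0.8, beta=1.2,
)
stream_dict, truth = simulate_photon_stream(config, duration=120.0, seed=4)
stream = PhotonStream.from_dict(stream_dict)
print(f"simulated {len(stream.timestamps)} photons, {len(truth)} true bursts")

bursts = search_bursts(stream, m=10, rate_factor=1.7, min_size=20)
print(f"detected {len(bursts)} bursts "
      f"(background {bursts.background['all']:.0f} Hz merged)")

factors = estimate_factors(bursts)
print(f"recovered corrections: α = {factors.alpha:.3f}, δ = {factors.delta:.3f}, "
      f"γ = {factors.gamma:.2f}, β = {factors.beta:.2f}")

corrected = correct_bursts(bursts, factors)
kept = filter_bursts(bursts, corrected, s_range=(0.25, 0.75))
print(f"{len(kept)} doubly-labelled bursts after S-window and ALEX-2CDE filters")

fit = fit_efret_distribution(kept, force=2)
for mean, sd, weight in fit.components:
    print(f"population: E = {mean:.3f} ± {sd:.3f} (weight {weight:.2f})")

print(
    "\nThe corrected population means recover the simulated E = 0.2 / 0.6 "
    "ground truth; α comes from donor-only bursts, δ from acceptor-only "
    "bursts, and γ/β from the two FRET populations' positions in the "
    "E-S plane."
)
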