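# interdom

Integrative analysis of inter-domain dynamics in multi-domain proteins.

Chaperones like *E. coli* SurA — a core domain plus two peptidyl-prolyl
isomerase domains (P1, P2) on flexible linkers — change their domain
arrangement in solution and upon substrate binding. No single technique
resolves this: crystal structures freeze one arrangement, cross-linking mass
spectrometry (XL-MS) reports which residue pairs come close in solution,
single-molecule FRET reports inter-domain distance distributions and their
dynamics, and hydrogen–deuterium exchange MS (HDX-MS) maps binding-induced
protection. `interdom` implements the computational layer that ties these
together, for structural biologists who have such data (or want to prototype
the analysis on simulated data before collecting it):

- **Cross-link validation** — straight-line (SLD) and solvent-accessible
  surface distances (SASD, Jwalk-style voxel Dijkstra) between restrained Cα
  pairs; DSBU links are feasible at SASD ≤ 35 Å, tag-transfer links at
  Euclidean ≤ 15 Å.
- **Restrained rigid-body annealing** — Metropolis Monte-Carlo with
  flat-well cross-link restraints (zero in [0, 27 Å], quadratic outside),
  geometric 3000 → 25 K cooling with a rising restraint weight, randomized
  starts, energy-ranked ensembles.
- **AV-FRET prediction** — dye accessible volumes by hard-sphere grid
  search; E = 1/(1 + (r/R0)⁶) distributions from structures (R0 = 60 Å for
  Alexa 488/594).
- **ALEX smFRET burst analysis** — background estimation, sliding-window
  burst search, the standard correction cascade (background → α donor
  leakage → δ direct excitation → γ, β normalisations), S-window and
  ALEX-2CDE filtering, Gaussian-mixture E fits, and burst variance analysis
  (BVA) against the shot-noise limit sqrt(E(1−E)/n).
- **Differential HDX-MS** — per-peptide summed uptake differences over four
  timepoints with a pooled 99% confidence threshold and Wood's-plot
  protected/deprotected classification.
- **Binding models** — Hill isotherm fits
  S_obs = S_U + (S_B − S_U)·[L]^n/(K_D^n + [L]^n) and the Perrin anisotropy
  relation r = r0/(1 + τ/T_r).
- **Synthetic data** — seeded generators for every input type (toy
  multi-domain structures with ground truth, cross-link tables, ALEX photon
  streams with static or switching populations, HDX uptake tables, noisy
  isotherms), so the full pipeline runs with no downloads.

## Worked example

`examples/04_burst_analysis.py` simulates 120 s of ALEX photons containing
two FRET populations (E = 0.2 and 0.6) plus donor-only and acceptor-only
species, with correction factors α = δ = 0.05, γ = 0.8, β = 1.2 applied by
the forward model, then recovers everything from the photon stream alone:

```
simulated 503662 photons, 1889 true bursts
detected 1718 bursts (background 1192 Hz merged)
recovered corrections: α = 0.052, δ = 0.054, γ = 0.81, β = 1.20
821 doubly-labelled bursts after S-window and ALEX-2CDE filters
population: E = 0.202 ± 0.062 (weight 0.51)
population: E = 0.583 ± 0.064 (weight 0.49)
```

The two corrected population means land on the simulated ground truth, the
donor-leakage factor α is recovered from the donor-only subpopulation via
α = E_app/(1 − E_app), and γ/β come from the positions of the two FRET
populations in the E–S plane. `examples/05_burst_variance_analysis.py`
continues with BVA: a static population sits on the shot-noise arc while a
two-state population switching ~10× per burst lies far above it — the
signature of sub-millisecond inter-domain motion.

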