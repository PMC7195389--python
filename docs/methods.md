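# Methods

`interdom` implements the computational core of an integrative study of
inter-domain dynamics in a multi-domain protein — the periplasmic chaperone
SurA is the motivating case, with a core domain (N- plus C-terminal regions
of the chain) and two peptidyl-prolyl isomerase domains (P1, P2) connected by
flexible linkers. Each section below describes one stage: the model, its
assumptions, the parameters that matter, and the numerical choices made where
the design was genuinely open.

## Structures and domain partitions

Structures are parsed from PDB text (gemmi behind the module surface),
keeping the source residue numbering — for SurA, gene numbering including the
signal peptide, so the mature chain spans residues 21–428. A domain partition
maps labels to lists of closed residue intervals; one domain may own several
discontiguous ranges (SurA's core = 21–170 plus 390–428 in the shipped
default, with P1 = 171–280 and P2 = 281–389). These boundaries are
approximate by necessity — the structural literature does not pin exact
linker residues — and are configurable through a small YAML file. Residue
pairs classify as intra-domain when they share a label, else inter-domain;
counts that depend on boundary placement should be read with that caveat.

Missing residues are rebuilt as single Cα beads: linear interpolation between
the flanking anchors, then a position-based relaxation that projects every
consecutive Cα–Cα distance toward the 3.8 Å virtual bond (tolerance ± 0.2 Å)
while pushing beads at least ~3 Å off existing atoms. This is deliberately
coarse — no side chains, no torsion statistics — because downstream use is
distance computation only; rebuilt residues carry a flag so cross-links that
touch them can be reported separately.

## Cross-link distance validation

Two distance conventions, matching the two chemistries:

- **DSBU** (Lys-reactive, ~27–30 Å straight-line span): satisfaction is
  decided on the **solvent-accessible surface distance (SASD)** with a 35 Å
  cutoff, boundary inclusive. SASD is the length of the shortest path between
  the two Cα atoms that stays in solvent: space is voxelised (1.0 Å default
  spacing, 0.5–2.0 allowed), a voxel is accessible when farther than
  `vdW + probe` = 1.8 + 1.4 Å from every atom centre, and Dijkstra's
  algorithm runs on the 26-connected accessible-voxel graph with Euclidean
  edge weights. The reported SASD is the minimum over accessible voxels
  v_a, v_b within 5 Å of each Cα of `|Cα_A − v_a| + path(v_a, v_b) +
  |v_b − Cα_B|`, implemented exactly with a virtual source node; an endpoint
  with no accessible voxel within 5 Å is buried and the link unreachable
  (counted as violated). By the triangle inequality SASD ≥ SLD always.
- **Tag-transfer** (photoactivatable diazirine, short-range): Euclidean
  Cα–Cα ≤ 15 Å, inclusive.

The straight-line distance band 27–30 Å for DSBU is carried as an annotation
only. In free space the voxel SASD converges to the straight-line distance
within about one grid spacing; refining the grid 2.0 → 1.0 Å moves free-space
values by less than one coarse spacing. The test suite checks the scipy-based
path search against an independent networkx Dijkstra on the identical graph.

## Rigid-body restrained annealing

Domains move as rigid bodies in a Cα representation; linker residues are free
beads joined by harmonic virtual bonds at 3.8 Å. The full energy is

    E(T) = w_xl(T) · Σ flat-well(d_ij) + Σ soft-sphere + Σ harmonic bonds

with a flat-well restraint per cross-link (zero inside [0, upper], quadratic
outside, k = 1), a quadratic soft-sphere penalty for non-bonded Cα pairs
closer than 5.5 Å (intra-domain pairs are rigid and excluded), and Metropolis
Monte-Carlo sampling: per move either one mobile domain is rotated (≤ 5°) and
translated (≤ 2 Å) about its centroid or one linker bead is displaced, all
scaled by √(T/T_start). Temperature drops geometrically 3000 → 25 K over 60
steps of 500 moves, while the restraint weight ramps geometrically 0.1 → 30,
so the hot phase explores and the cold phase enforces. Each repeat starts
from a randomized conformation (mobile domains translated uniformly within
20 Å and rotated within 90°; the largest domain anchors the frame), and the
best conformation visited — judged at the final restraint weight — is kept.
Repeats are ranked by total energy, ties broken by restraint energy then run
index.

Two parameters deserve explanation because their obvious values turned out to
be inconsistent with each other:

- **Flat-well upper bound, 27 Å.** Satisfaction is *reported* on SASD ≤ 35 Å
  but *sampled* on the Euclidean distance (computing SASD per Monte-Carlo
  move is prohibitive). Around compact domains the surface detour factor
  SASD/SLD reaches ~1.3–1.4, so a Euclidean well of 30 Å admits models whose
  links then fail the SASD criterion. 27 Å — the low end of the DSBU
  feasibility band — keeps the two conventions coherent: 27 × 1.3 ≈ 35.
- **Clash onset, 5.5 Å.** A water-probe-accessible channel between two atoms
  needs ≥ 2 × (1.8 + 1.4) = 6.4 Å between their centres. With a 4 Å Cα
  soft-sphere onset, inter-domain interfaces pack so tightly that no solvent
  path crosses them and satisfied restraints become SASD-unreachable; 5.5 Å
  is also the more physical excluded-volume scale for a residue-level model.

With these defaults the synthetic recovery study (three domains, 12 true
links, 20 repeats) returns a lowest-energy model satisfying ≥ 11/12 links
with inter-domain centroid distances within 5 Å RMS of ground truth across
generator seeds.

Because restraints only pull inward, the protocol drives compact states;
extended conformations that coexist in solution are invisible to it — that is
what the smFRET stages are for.

## Dye accessible volumes and FRET prediction

A dye tethered at a residue is modelled by a hard-sphere grid search: all
points within the linker length (20 Å default) of the attachment Cα that keep
at least `dye radius + atom radius` = 3.5 + 1.8 Å clearance from every
protein atom (the attachment residue itself is excluded, since the dye
replaces its side chain). The linker width parameter is carried for
provenance but unused — no linker-path self-avoidance is modelled. Predicted
E distributions come from sampling dye-position pairs uniformly from the two
volumes, converting r to E = 1/(1 + (r/R0)⁶) with R0 = 60 Å for the
Alexa 488/594 pair, and summarising with a ≤ 2-component Gaussian mixture.
κ² = 2/3 (free dye rotation) is assumed throughout; the steady-state
anisotropy module provides the standard sanity check for that assumption.

## ALEX burst analysis

Photon streams carry integer timestamps, a detector channel (donor/acceptor)
and an alternation spec: 40 μs period, donor excitation in the first 40%,
acceptor excitation in [50%, 90%), the rest dark (the duty cycle is stated as
a single number in the source protocols; the 40/40/20 split is this package's
reading, and it is configurable). Each photon therefore belongs to one of
four streams: DD, AD, DA, AA.

- **Background** is estimated per stream by a censored-exponential fit of
  inter-photon delays: delays above their 80–90th percentile are
  background-dominated even when bursts are present, and the tail mean above
  a threshold `th` estimates `th + 1/rate`. Estimates are averaged over 30 s
  slices.
- **Burst search** is the all-photon sliding-window criterion: the window of
  m = 10 consecutive photons starting at a photon qualifies when its local
  rate is ≥ 1.7 × the merged background rate. Maximal runs of qualifying
  window starts form bursts (each run extends m − 1 photons past its last
  start); bursts below 20 photons are dropped. Marking window *starts* rather
  than window members is what keeps the low 1.7 threshold usable: isolated
  background coincidences seed runs of length ~1 (≈ 10 photons, below the
  minimum), while genuine bursts produce long consecutive runs. A pure
  background trace yields < 1 false burst per 10 minutes.
- **Corrections** follow the standard FRET workflow: background subtraction
  (rate × burst duration per stream), donor leakage α estimated from
  donor-only bursts (α = E_app/(1−E_app) of the DO population, selected by
  S_app > 0.85), direct acceptor excitation δ from acceptor-only bursts
  (δ = S_app/(1−S_app), S_app < 0.15), then F_A|D = AD − α·DD − δ·AA,
  F_D|D = γ·DD, F_A|A = AA/β. γ and β may be supplied or are estimated by the
  two-population method: 1/S vs E is linear across FRET species
  (1/S = 1 + βγ + β(1−γ)E), and the line is fit through the centroids of the
  two populations (clustered by a 2-component mixture on E after α/δ
  correction, centrally trimmed, ratio-of-sums statistics). Fitting through
  population centroids rather than regressing over individual bursts avoids
  the errors-in-variables bias that per-burst noise induces; bursts flagged
  by ALEX-2CDE are excluded from the calibration because temporally merged
  double-molecule events corrupt the centroids.
- **Filtering** keeps bursts with corrected S in [0.25, 0.75] (closed) and an
  ALEX-2CDE score ≤ 10. The score compares exponential-kernel densities
  (τ = 100 μs) of donor-excitation and acceptor-excitation photon times at
  each photon: `100 − 50·(BR_DexAex + BR_AexDex)`, where each bracket-ratio
  term averages the cross-stream/own-stream density ratio (own-stream density
  keeps the self photon so the ratio is bounded). Well-mixed dual-labelled
  bursts score near 0, single-labelled bursts near 100.
- **E histograms** are summarised by a Silverman-bandwidth KDE plus a
  maximum-likelihood Gaussian mixture with 1 or 2 components chosen by BIC
  (or forced).
- **Burst variance analysis** recomputes the acceptor fraction E in
  consecutive non-overlapping windows of n = 5 donor-excitation photons per
  burst, takes the per-burst standard deviation (ddof = 1) across windows,
  bins bursts by their overall acceptor fraction, and compares bin means with
  the binomial shot-noise arc sqrt(E(1−E)/n). Static populations sit on the
  arc (within ~3%, the small-sample bias of the sd estimator); two-state
  switching around 10 transitions per burst lifts bin means above it by many
  standard errors.

## Differential HDX-MS

Peptide-level analysis only. For each peptide the summed difference
ΔD_sum = Σ_t (mean_bound(t) − mean_apo(t)) over the four exposure times
(0.5, 2, 30, 120 min) is compared with a global threshold: per-timepoint
variances pooled across peptides, summed in quadrature over timepoints, and
scaled by the Student-t quantile at 1 − α/2 with Welch–Satterthwaite degrees
of freedom aggregated over all contributing cells (with hundreds of peptides
this approaches the normal quantile, which is what makes the α = 0.01
false-positive calibration land on 1%). Classification: protected if
ΔD_sum < −threshold, deprotected if > +threshold. A per-peptide Welch
variant is available (`method="perpeptide"`); the global pooled line is the
default because it is the established convention for Wood's plots. Uptake is
used in raw Da without back-exchange correction; the 82% D₂O fraction lives
only in the simulator.

## Binding models

The Hill isotherm is implemented as
S_obs = S_U + (S_B − S_U)·[L]^n/(K_D^n + [L]^n). The variant with a bare K_D
in the denominator (dimensionally consistent only at n = 1) is selectable via
`printed_form=True` for strict reproduction of legacy fits; the two coincide
exactly at n = 1, the regime of the motivating measurement (K_D ≈ 800 nM,
16-point twofold dilution from 100 μM). Fits are unweighted nonlinear least
squares (lmfit) with K_D > 0 and n ∈ (0.1, 5), initialised at the geometric
mean of the concentration range and n = 1. Steady-state anisotropy follows
the Perrin relation r = r0/(1 + τ/T_r).

## Synthetic data: what it emulates, what it does not

Every stage has a seeded generator so the entire pipeline runs and is tested
without downloads:

- **Toy structures**: compact self-avoiding Cα walks (40 residues per domain
  by default) joined by 8-residue linkers, placed in a "closed" conformation
  (centroids on a polygon of side 22 Å) or an "open" one (extended chain,
  centroid steps ≥ ~30 Å). Domain shapes depend only on the seed, so the two
  conformations of one seed differ by rigid transforms alone. Every 4th
  residue is a designated cross-linkable site.
- **Cross-links**: true links sampled among inter-domain site pairs with
  ground-truth Euclidean distance ≤ 25 Å *and* SASD ≤ 35 Å (a
  surface-reactive reagent cannot form a link without a solvent path); decoys
  at > 35 Å.
- **Photon streams**: burst-level — Poisson burst arrivals (15 s⁻¹),
  lognormal sizes (mean 90 photons), 1 ms duration, four-stream counts from
  the forward model implied by each species' (E, S) and the configured
  (α, δ, γ, β), Poisson background per stream, ALEX windows respected.
  Two-state species modulate the acceptor-routing probability along a
  simulated Markov trajectory (exact for γ = 1). There is no diffusion, no
  size–duration correlation, and no photophysics (blinking, bleaching), so
  passing tests validate the estimators on photon statistics, not detector
  physics.
- **HDX**: lumped amide kinetics, uptake(t) = 0.82·Σ(1 − e^(−k·t/PF)) with
  per-amide rates log-uniform over 10⁻²·⁵–10⁰·⁵ min⁻¹, protection factors per
  peptide, Gaussian noise (sd 0.05 Da), 4 replicates. No isotope envelopes,
  no back-exchange, no peptide overlap structure.
- **Isotherms**: the Hill equation on the study's dilution design plus
  Gaussian noise.

## Problem sizes used in the shipped checks

The acceptance script and test suite run at desk scale: 30 two-domain toys
(≤ 50 residues, 1.5 Å grid) for the SASD oracle; one three-domain recovery
study with 12 links and 20 annealing repeats; 240 s of simulated photons
(~3500 detected bursts) for the correction round trip and 120 s each for the
BVA controls; 1000 null peptides for the HDX calibration; 100 noisy
isotherm repeats. These sizes make every stage's statistical target
measurable while keeping a full run in minutes.

## Known limitations

- Cα-only geometry everywhere; no side-chain or atomic-detail modelling.
- The annealer's energies are not physical free energies; rankings are
  meaningful only within an ensemble run with one parameter set.
- SASD depends mildly on grid spacing and the uniform van der Waals radius;
  values near the 35 Å cutoff can flip classification between spacings.
- γ/β estimation needs two separated FRET populations; single-population
  measurements must supply them.
- The Wood's-plot threshold assumes roughly homogeneous replicate noise
  across peptides (pooling); strongly heteroscedastic data should use the
  per-peptide variant.
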