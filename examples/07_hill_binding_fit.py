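"""Fit a binding isotherm with the Hill equation.

Simulates a 16-point twofold dilution series (100 μM down to ~3 nM) around
K_D = 800 nM with 2% signal noise and fits
S_obs = S_U + (S_B − S_U)·[L]^n / (K_D^n + [L]^n).
"""

from interdom.binding import fit_hill, steady_state_anisotropy
from interdom.synthetic import simulate_isotherm

iso = simulate_isotherm(s_u=0.0, s_b=1.0, kd=8e-7, n=1.0, noise_sd=0.02, seed=1)
fit = fit_hill(iso)

print(f"K_D = {fit.kd * 1e9:.0f} nM (± {fit.stderr['kd'] * 1e9:.0f})")
print(f"n   = {fit.n:.2f} (± {fit.stderr['n']:.2f})")
print(f"S_U = {fit.s_u:.3f}, S_B = {fit.s_b:.3f}")

r = steady_state_anisotropy(r0=0.4, tau=4.0, t_r=2.0)
print(f"\nPerrin check: r0 = 0.4, τ = 4 ns, T_r = 2 ns → r = {r:.4f}")

print(
    "\nThe fitted K_D recovers the generating 800 nM within noise; at "
    "[L] = K_D the curve passes through the half-saturation signal. The "
    "anisotropy relation links steady-state depolarisation to the ratio of "
    "fluorescence lifetime and rotational correlation time — low r means a "
    "freely rotating dye, which justifies κ² = 2/3 in FRET distance "
    "conversions."
)
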