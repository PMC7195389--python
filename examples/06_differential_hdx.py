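"""Differential HDX-MS with Wood's-plot classification.

Simulates peptide-level deuterium uptake for an apo and a ligand-bound state
(4 timepoints: 0.5, 2, 30, 120 min; 4 replicates; 82% D2O) with five peptides
protected 10-fold in the bound state, then classifies every peptide by its
summed uptake difference against a 99% confidence threshold.
"""

from interdom.hdx import load_uptake, woods_analysis
from interdom.synthetic import make_hdx_profiles, simulate_hdx

profiles = make_hdx_profiles(n_peptides=40, protected={i: 10.0 for i in range(5)}, seed=9)
table = simulate_hdx(profiles, noise_sd=0.05, seed=10)
uptake = load_uptake(table.to_csv(index=False))

result = woods_analysis(uptake, state_a="apo", state_b="bound", alpha=0.01)
print(f"global 99% threshold: ±{result['threshold'].iloc[0]:.3f} Da")
print(result[result["class"] != "not significant"]
      [["start", "end", "dd_sum", "class"]].round(3).to_string(index=False))
counts = result["class"].value_counts()
print(f"\nclassified: {dict(counts)}")

print(
    "\nNegative summed differences (bound minus apo) mean protection from "
    "exchange — the five planted binding-site peptides stand far outside "
    "the band. The remaining peptides carry pure noise, so at the 99% level "
    "roughly one borderline call per ~100 peptides is expected."
)
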