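"""Validate cross-links against a structure: SLD, SASD and satisfaction.

Builds a three-domain toy protein with a known closed conformation, simulates
a DSBU cross-link table (12 geometrically true links, 2 decoys), and
classifies every link on both the true structure and an open decoy.
"""

from interdom.partition import assign_domains
from interdom.synthetic import make_toy_multidomain, simulate_crosslinks
from interdom.xl import classify_crosslinks, read_crosslink_table

closed = make_toy_multidomain(seed=1, conformation="closed")
open_decoy = make_toy_multidomain(seed=1, conformation="open")
csv, truth = simulate_crosslinks(closed, n_true=12, n_false=2, seed=1)
links = read_crosslink_table(csv)

for name, gt in (("closed (truth)", closed), ("open (decoy)", open_decoy)):
    assignment = assign_domains(gt.structure, gt.partition)
    table, summary = classify_crosslinks(links, gt.structure, assignment, spacing=1.5)
    print(f"\n{name}: {summary['satisfied']}/{summary['evaluable']} links satisfied")
    print(table[["residue_a", "residue_b", "sld", "sasd", "satisfied", "pair_label"]]
          .round(1).to_string(index=False))

print(
    "\nA DSBU link is satisfied when the solvent-accessible surface distance "
    "(SASD) between the two Cα atoms is ≤ 35 Å. On the generating (closed) "
    "conformation all true links pass; on the open decoy most fail, which is "
    "exactly the signal that drives restrained modelling."
)
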