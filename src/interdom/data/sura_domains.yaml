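# Approximate SurA domain boundaries, gene numbering (signal peptide included).
# core owns two discontiguous ranges (N- and C-terminal regions of the chain);
# P1 and P2 are the parvulin-like PPIase domains.
core:
  - "21-170"
  - "390-428"
P1:
  - "171-280"
P2:
  - "281-389"
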