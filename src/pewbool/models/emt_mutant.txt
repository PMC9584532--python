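# EMT network with PEW-weighted feedback edges (mutant variant).
# TGFB is a held input; drive it with a pulse perturbation.
SMAD* = TGFB
d1* = TGFB
d2* = d1
d3* = d2
d4* = d3
d5* = d4
d6* = d5
a1* = TGFB
a2* = a1
a3* = a2
SNAI1* = d6 or [0.95,0.0] SNAI1
ZEB* = (SMAD or SNAI1) and not miR200
miR200* = not [0.05,0.0] ZEB and not a3
Ecad* = not ZEB
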