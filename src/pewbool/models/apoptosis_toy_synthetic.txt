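# SYNTHETIC miniature of the apoptosis-commitment module of a cell cycle
# network. This is NOT the published 89-node model (load that from its own
# rule file); it only mirrors the motif targeted by the edge-weakening
# recipe: the CyclinB-Cdk1 complex inhibits three anti-apoptotic nodes, and
# the caspase-activated DNase CAD latches ON (commitment to apoptosis) once
# all three are lost at the same time. Cdk1 and CyclinB are held inputs.
MCL1* = not (Cdk1 and CyclinB)
BCLXL* = not (Cdk1 and CyclinB)
BCL2* = not (Cdk1 and CyclinB)
CAD* = CAD or (not MCL1 and not BCLXL and not BCL2)
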