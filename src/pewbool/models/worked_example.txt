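# Worked example: the C -> A edge weakened to fire only 30% of the time
# when C is ON, and never when C is OFF. B and C are held inputs.
A* = B and [0.3,0] C
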