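# Two-node negative feedback loop: a synchronous limit cycle of length 4.
A* = not B
B* = A
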