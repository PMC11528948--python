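# Default CYP2D6 inhibitor-strength table. Drugs absent from this table are
# treated as non-inhibitors. CYP2D6 has no known inducers; inducer entries
# are rejected by the engine.
paroxetine: strong
fluoxetine: strong
bupropion: strong
citalopram: weak
sertraline: weak
escitalopram: weak
clomipramine: weak
levomepromazine: weak
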