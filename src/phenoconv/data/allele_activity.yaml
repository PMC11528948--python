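# Default CYP2D6 star-allele activity values (override with your own table).
# normal function -> 1.0, decreased function -> 0.5, no function -> 0.0
"*1": 1.0
"*2": 1.0
"*35": 1.0
"*9": 0.5
"*10": 0.5
"*17": 0.5
"*29": 0.5
"*41": 0.5
"*3": 0.0
"*4": 0.0
"*5": 0.0
"*6": 0.0
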