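variable C levels 0..2

rule K1: C = 0 >> C = 1
rule K2: C = 1 >> C = 2
rule K3: C = 2 >> C = 0

initial: 
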