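variable M levels 0..2
variable S1
variable S2

rule R1: M >= 1 >> S1+
rule R2: M >= 2 >> S2+
rule R3: M < 1 >> S1-
rule R4: M < 2 >> S2-

initial: M = 1
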