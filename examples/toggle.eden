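variable M
variable S

rule T1: M- >> M+
rule T2: M+ >> M-
rule T3: M+ >> S+
rule T4: M- >> S-

initial: 
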