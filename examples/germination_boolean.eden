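variable M
variable S

rule R1: M+ >> S+
rule R2: M- >> S-

initial: M+
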