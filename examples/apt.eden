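variable A
variable P
variable T

rule R1: A+ and P+ >> P-
rule R2: A+ and T+ >> T-
rule R3: P+ and T+ >> T-
rule R4: A+ and P- >> A-

initial: A+, P+, T+
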