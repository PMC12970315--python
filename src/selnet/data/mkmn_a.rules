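# MKMN-style two-network case study, variant A ("pathological": force C9 off).
# Differs from variant B by the r3 -> C2 linkage and the C2 -> C4 dependency,
# which funnel every activation route through the C6/C7/r3 branch.
input C1
input C3
input C6
input C7
C2 = C1 & r3
C4 = C3 & C2
r1 = C1 & C2
C5 = r1
r2 = C3 & C4
C8 = r2
r3 = C6 & C7
r4 = C5
C9 = r4 | C8 | r3
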