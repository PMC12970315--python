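# linear chain A -> B -> C; exactly one elementary mode {r1, r2}
# boundary: A C
r1	A -> B	1
r2	B -> C	1
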