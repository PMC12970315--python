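# two disjoint routes A -> C; exactly two elementary modes
# boundary: A C
r1	A -> B	1
r2	B -> C	1
r3	A -> D	1
r4	D -> C	1
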