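# 3-cycle A -> B -> C -> A with one entry and one exit exchange;
# elementary modes: the internal cycle {r1,r2,r3} and the through-path
# {e_in, r1, e_out} (fixed by the rational null space, which is 2-D here)
# boundary: X Y
e_in	X -> A	1
r1	A -> B	1
r2	B -> C	1
r3	C -> A	1
e_out	B -> Y	1
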