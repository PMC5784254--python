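# LRxGI spacer column frequencies (9 columns x 20 residues)
# synthetic defaults: the motif definition constrains only the
# LR/GI anchors, so spacer composition is package config
position	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	0.005882	0.005882	0.005882	0.700000	0.005882	0.100000	0.005882	0.005882	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882
2	0.700000	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.100000	0.005882	0.005882
3	0.005882	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.100000	0.005882	0.005882	0.005882	0.700000	0.005882
4	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.700000	0.005882	0.005882	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882
5	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.100000	0.005882	0.100000	0.005882	0.005882	0.005882	0.700000	0.005882	0.005882	0.005882	0.005882
6	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.700000	0.005882	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.100000	0.005882	0.005882
7	0.005882	0.005882	0.700000	0.005882	0.100000	0.005882	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882
8	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.700000	0.100000	0.005882	0.005882	0.005882	0.005882	0.100000
9	0.005882	0.005882	0.100000	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.005882	0.100000	0.005882	0.700000	0.005882	0.005882	0.005882
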