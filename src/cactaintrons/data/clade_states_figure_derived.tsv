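clade	G	I	II	III	consensus_exons
alpha	0	0	0	0	1
beta	0	0	1	1	3
gamma	1	1	1	1	5
delta	0	1	0	1	3
epsilon	0	0	1	1	3
zeta	0	0	0	0	2
eta	0	1	1	1	4
theta	0	0	0	1	3
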