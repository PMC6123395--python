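# soilcue feature table v1 — 6-sample toy matrix for worked examples
group	low	low	low	high	high	high
feature_id	L1	L2	L3	H1	H2	H3
F0001	5.0	4.0	6.0	0.0	0.0	0.0
F0002	0.0	0.0	0.0	3.0	2.0	4.0
F0003	2.0	2.0	2.0	2.0	2.0	2.0
F0004	1.0	0.0	3.0	0.5	0.0	0.0
F0005	0.0	0.0	0.0	0.0	0.0	0.0
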