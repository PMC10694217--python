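structure	A0B_rotation	B7	B37	B38	B30	A21	A23	B19
F_thermalis_7521	Y	Y	Y	Y	Y	Y	N	N
Synechococcus_7335	Y	Y	Y	Y	Y	Y	N	Y
H_hongdechloris	Y	Y	Y	Y	Y	Y	Y	N
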