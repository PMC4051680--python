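motif_id	motif_sequence	total	modified	fraction	mean_ipd_ratio	mean_coverage	position_modified
CPGDMM1	TATANNNATNA	97	35	0.36	1.71	66.00	-1
CPGDMM2	WNYANTGAW	369	91	0.25	1.77	84.71	-3
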