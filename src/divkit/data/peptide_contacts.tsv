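# MHC class I alpha1/alpha2 positions (mature numbering) predicted to contact
# the bound 9-mer peptide within 4.0 A, with the peptide positions touched.
# source=text: position named in the study narrative for these lineages;
# source=canonical: completed from the canonical class I groove-contact
# assignments (flagged because the figure cells were not machine-readable).
mhc_pos	peptide_positions	source
5	1	canonical
7	1,2	text
9	2	text
24	2	text
45	2	text
59	1	canonical
62	1,2,3	text
63	1,2	text
66	2,3	text
67	2	text
69	3	canonical
70	2,3	text
73	3	text
74	2,3	canonical
76	8	canonical
77	8,9	canonical
80	8,9	canonical
81	9	text
84	9	canonical
95	3,5	text
97	5	text
99	3,5	text
114	4,5	text
116	9	text
118	9	canonical
123	9	canonical
143	8,9	canonical
146	7,8	canonical
147	7,8	canonical
152	6,7	text
155	6,7,8	text
156	3,6,7	text
159	1,2	canonical
163	1,2	canonical
167	1	canonical
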