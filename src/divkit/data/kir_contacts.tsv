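# MHC class I positions (mature numbering) contacting the KIR D1/D2 domains
# at the C-terminal end of the peptide-binding groove. critical=1 marks the
# five positions whose substitution markedly changes KIR3DL1 affinity in
# mutational studies. source as in peptide_contacts.tsv.
mhc_pos	critical	source
76	0	canonical
79	0	canonical
80	1	text
81	0	canonical
82	0	canonical
83	1	text
84	0	text
89	0	canonical
90	0	canonical
142	1	text
145	0	canonical
146	1	text
149	1	text
151	0	text
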