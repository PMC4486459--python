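# Symmetric contact energies (kcal/mol per heavy-atom contact) over the
# 18 atom classes of atom_types.tsv. Constructed from per-class transfer
# energies e_ij = (g_i + g_j)/2: burying apolar carbon/sulfur is
# favourable (negative), burying charged or polar nitrogen/oxygen costs
# energy (positive). Synthetic surrogate following the structure of
# atomic-contact-energy potentials; not a published matrix.
type	N_AMIDE	CA	C_CARBONYL	O_CARBONYL	O_TERM	GLY_CA	PRO_N	C_BETA	C_ALIPH	C_AROM	N_ARG	N_LYS	N_RING	N_AMIDE_SC	O_AMIDE	O_CARBOXYL	O_HYDROXYL	S
N_AMIDE	+0.100	+0.025	+0.050	+0.100	+0.225	+0.010	+0.060	-0.025	-0.050	-0.040	+0.200	+0.250	+0.090	+0.110	+0.110	+0.225	+0.110	-0.025
CA	+0.025	-0.050	-0.025	+0.025	+0.150	-0.065	-0.015	-0.100	-0.125	-0.115	+0.125	+0.175	+0.015	+0.035	+0.035	+0.150	+0.035	-0.100
C_CARBONYL	+0.050	-0.025	+0.000	+0.050	+0.175	-0.040	+0.010	-0.075	-0.100	-0.090	+0.150	+0.200	+0.040	+0.060	+0.060	+0.175	+0.060	-0.075
O_CARBONYL	+0.100	+0.025	+0.050	+0.100	+0.225	+0.010	+0.060	-0.025	-0.050	-0.040	+0.200	+0.250	+0.090	+0.110	+0.110	+0.225	+0.110	-0.025
O_TERM	+0.225	+0.150	+0.175	+0.225	+0.350	+0.135	+0.185	+0.100	+0.075	+0.085	+0.325	+0.375	+0.215	+0.235	+0.235	+0.350	+0.235	+0.100
GLY_CA	+0.010	-0.065	-0.040	+0.010	+0.135	-0.080	-0.030	-0.115	-0.140	-0.130	+0.110	+0.160	+0.000	+0.020	+0.020	+0.135	+0.020	-0.115
PRO_N	+0.060	-0.015	+0.010	+0.060	+0.185	-0.030	+0.020	-0.065	-0.090	-0.080	+0.160	+0.210	+0.050	+0.070	+0.070	+0.185	+0.070	-0.065
C_BETA	-0.025	-0.100	-0.075	-0.025	+0.100	-0.115	-0.065	-0.150	-0.175	-0.165	+0.075	+0.125	-0.035	-0.015	-0.015	+0.100	-0.015	-0.150
C_ALIPH	-0.050	-0.125	-0.100	-0.050	+0.075	-0.140	-0.090	-0.175	-0.200	-0.190	+0.050	+0.100	-0.060	-0.040	-0.040	+0.075	-0.040	-0.175
C_AROM	-0.040	-0.115	-0.090	-0.040	+0.085	-0.130	-0.080	-0.165	-0.190	-0.180	+0.060	+0.110	-0.050	-0.030	-0.030	+0.085	-0.030	-0.165
N_ARG	+0.200	+0.125	+0.150	+0.200	+0.325	+0.110	+0.160	+0.075	+0.050	+0.060	+0.300	+0.350	+0.190	+0.210	+0.210	+0.325	+0.210	+0.075
N_LYS	+0.250	+0.175	+0.200	+0.250	+0.375	+0.160	+0.210	+0.125	+0.100	+0.110	+0.350	+0.400	+0.240	+0.260	+0.260	+0.375	+0.260	+0.125
N_RING	+0.090	+0.015	+0.040	+0.090	+0.215	+0.000	+0.050	-0.035	-0.060	-0.050	+0.190	+0.240	+0.080	+0.100	+0.100	+0.215	+0.100	-0.035
N_AMIDE_SC	+0.110	+0.035	+0.060	+0.110	+0.235	+0.020	+0.070	-0.015	-0.040	-0.030	+0.210	+0.260	+0.100	+0.120	+0.120	+0.235	+0.120	-0.015
O_AMIDE	+0.110	+0.035	+0.060	+0.110	+0.235	+0.020	+0.070	-0.015	-0.040	-0.030	+0.210	+0.260	+0.100	+0.120	+0.120	+0.235	+0.120	-0.015
O_CARBOXYL	+0.225	+0.150	+0.175	+0.225	+0.350	+0.135	+0.185	+0.100	+0.075	+0.085	+0.325	+0.375	+0.215	+0.235	+0.235	+0.350	+0.235	+0.100
O_HYDROXYL	+0.110	+0.035	+0.060	+0.110	+0.235	+0.020	+0.070	-0.015	-0.040	-0.030	+0.210	+0.260	+0.100	+0.120	+0.120	+0.235	+0.120	-0.015
S	-0.025	-0.100	-0.075	-0.025	+0.100	-0.115	-0.065	-0.150	-0.175	-0.165	+0.075	+0.125	-0.035	-0.015	-0.015	+0.100	-0.015	-0.150
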