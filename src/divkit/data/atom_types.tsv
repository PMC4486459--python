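# Heavy-atom typing into 18 chemical classes for the contact-energy sum.
# residue "*" is a wildcard (backbone atoms of every residue). Hydrogens are
# never typed; heavy atoms matching no row fall back by element
# (C->C_ALIPH, N->N_AMIDE_SC, O->O_HYDROXYL, S->S).
residue	atom	type
*	N	N_AMIDE
*	CA	CA
*	C	C_CARBONYL
*	O	O_CARBONYL
*	OXT	O_TERM
GLY	CA	GLY_CA
PRO	N	PRO_N
ALA	CB	C_BETA
ARG	CB	C_BETA
ASN	CB	C_BETA
ASP	CB	C_BETA
CYS	CB	C_BETA
GLN	CB	C_BETA
GLU	CB	C_BETA
HIS	CB	C_BETA
ILE	CB	C_BETA
LEU	CB	C_BETA
LYS	CB	C_BETA
MET	CB	C_BETA
PHE	CB	C_BETA
SER	CB	C_BETA
THR	CB	C_BETA
TRP	CB	C_BETA
TYR	CB	C_BETA
VAL	CB	C_BETA
ILE	CG1	C_ALIPH
ILE	CG2	C_ALIPH
ILE	CD1	C_ALIPH
LEU	CG	C_ALIPH
LEU	CD1	C_ALIPH
LEU	CD2	C_ALIPH
VAL	CG1	C_ALIPH
VAL	CG2	C_ALIPH
THR	CG2	C_ALIPH
ALA	CB	C_BETA
MET	CG	C_ALIPH
MET	CE	C_ALIPH
LYS	CG	C_ALIPH
LYS	CD	C_ALIPH
LYS	CE	C_ALIPH
ARG	CG	C_ALIPH
ARG	CD	C_ALIPH
GLU	CG	C_ALIPH
GLN	CG	C_ALIPH
PRO	CB	C_ALIPH
PRO	CG	C_ALIPH
PRO	CD	C_ALIPH
PHE	CG	C_AROM
PHE	CD1	C_AROM
PHE	CD2	C_AROM
PHE	CE1	C_AROM
PHE	CE2	C_AROM
PHE	CZ	C_AROM
TYR	CG	C_AROM
TYR	CD1	C_AROM
TYR	CD2	C_AROM
TYR	CE1	C_AROM
TYR	CE2	C_AROM
TYR	CZ	C_AROM
TRP	CG	C_AROM
TRP	CD1	C_AROM
TRP	CD2	C_AROM
TRP	CE2	C_AROM
TRP	CE3	C_AROM
TRP	CZ2	C_AROM
TRP	CZ3	C_AROM
TRP	CH2	C_AROM
HIS	CG	C_AROM
HIS	CD2	C_AROM
HIS	CE1	C_AROM
ARG	CZ	N_ARG
ARG	NE	N_ARG
ARG	NH1	N_ARG
ARG	NH2	N_ARG
LYS	NZ	N_LYS
HIS	ND1	N_RING
HIS	NE2	N_RING
TRP	NE1	N_RING
ASN	ND2	N_AMIDE_SC
GLN	NE2	N_AMIDE_SC
ASN	OD1	O_AMIDE
GLN	OE1	O_AMIDE
ASP	OD1	O_CARBOXYL
ASP	OD2	O_CARBOXYL
GLU	OE1	O_CARBOXYL
GLU	OE2	O_CARBOXYL
ASP	CG	C_CARBONYL
GLU	CD	C_CARBONYL
ASN	CG	C_CARBONYL
GLN	CD	C_CARBONYL
SER	OG	O_HYDROXYL
THR	OG1	O_HYDROXYL
TYR	OH	O_HYDROXYL
CYS	SG	S
MET	SD	S
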