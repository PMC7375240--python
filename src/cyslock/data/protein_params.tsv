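# residue_name	atom_name	charge_e	sigma_A	epsilon_kcal
ALA	N	-0.10	3.25	0.170
ALA	CA	0.10	3.75	0.105
ALA	C	0.45	3.75	0.105
ALA	O	-0.45	2.96	0.210
ALA	CB	0.00	3.75	0.105
ALA	OXT	-0.45	2.96	0.210
ARG	N	-0.10	3.25	0.170
ARG	CA	0.10	3.75	0.105
ARG	C	0.45	3.75	0.105
ARG	O	-0.45	2.96	0.210
ARG	CB	0.00	3.75	0.105
ARG	CG	0.00	3.75	0.105
ARG	CD	0.10	3.75	0.105
ARG	NE	-0.40	3.25	0.170
ARG	CZ	0.80	3.75	0.105
ARG	NH1	0.25	3.25	0.170
ARG	NH2	0.25	3.25	0.170
ARG	OXT	-0.45	2.96	0.210
ASN	N	-0.10	3.25	0.170
ASN	CA	0.10	3.75	0.105
ASN	C	0.45	3.75	0.105
ASN	O	-0.45	2.96	0.210
ASN	CB	0.30	3.75	0.105
ASN	CG	0.55	3.75	0.105
ASN	OD1	-0.55	2.96	0.210
ASN	ND2	-0.30	3.25	0.170
ASN	OXT	-0.45	2.96	0.210
ASP	N	-0.10	3.25	0.170
ASP	CA	0.10	3.75	0.105
ASP	C	0.45	3.75	0.105
ASP	O	-0.45	2.96	0.210
ASP	CB	0.00	3.75	0.105
ASP	CG	0.36	3.75	0.105
ASP	OD1	-0.68	2.96	0.210
ASP	OD2	-0.68	2.96	0.210
ASP	OXT	-0.45	2.96	0.210
CYS	N	-0.10	3.25	0.170
CYS	CA	0.10	3.75	0.105
CYS	C	0.45	3.75	0.105
CYS	O	-0.45	2.96	0.210
CYS	CB	0.15	3.75	0.105
CYS	SG	-0.15	3.55	0.250
CYS	OXT	-0.45	2.96	0.210
GLN	N	-0.10	3.25	0.170
GLN	CA	0.10	3.75	0.105
GLN	C	0.45	3.75	0.105
GLN	O	-0.45	2.96	0.210
GLN	CB	0.00	3.75	0.105
GLN	CG	0.30	3.75	0.105
GLN	CD	0.55	3.75	0.105
GLN	OE1	-0.55	2.96	0.210
GLN	NE2	-0.30	3.25	0.170
GLN	OXT	-0.45	2.96	0.210
GLU	N	-0.10	3.25	0.170
GLU	CA	0.10	3.75	0.105
GLU	C	0.45	3.75	0.105
GLU	O	-0.45	2.96	0.210
GLU	CB	0.00	3.75	0.105
GLU	CG	0.00	3.75	0.105
GLU	CD	0.36	3.75	0.105
GLU	OE1	-0.68	2.96	0.210
GLU	OE2	-0.68	2.96	0.210
GLU	OXT	-0.45	2.96	0.210
GLY	N	-0.10	3.25	0.170
GLY	CA	0.10	3.75	0.105
GLY	C	0.45	3.75	0.105
GLY	O	-0.45	2.96	0.210
GLY	OXT	-0.45	2.96	0.210
HIS	N	-0.10	3.25	0.170
HIS	CA	0.10	3.75	0.105
HIS	C	0.45	3.75	0.105
HIS	O	-0.45	2.96	0.210
HIS	CB	0.00	3.75	0.105
HIS	CG	0.10	3.75	0.105
HIS	ND1	-0.40	3.25	0.170
HIS	CD2	0.10	3.75	0.105
HIS	CE1	0.30	3.75	0.105
HIS	NE2	-0.10	3.25	0.170
HIS	OXT	-0.45	2.96	0.210
ILE	N	-0.10	3.25	0.170
ILE	CA	0.10	3.75	0.105
ILE	C	0.45	3.75	0.105
ILE	O	-0.45	2.96	0.210
ILE	CB	0.00	3.75	0.105
ILE	CG1	0.00	3.75	0.105
ILE	CG2	0.00	3.75	0.105
ILE	CD1	0.00	3.75	0.105
ILE	OXT	-0.45	2.96	0.210
LEU	N	-0.10	3.25	0.170
LEU	CA	0.10	3.75	0.105
LEU	C	0.45	3.75	0.105
LEU	O	-0.45	2.96	0.210
LEU	CB	0.00	3.75	0.105
LEU	CG	0.00	3.75	0.105
LEU	CD1	0.00	3.75	0.105
LEU	CD2	0.00	3.75	0.105
LEU	OXT	-0.45	2.96	0.210
LYS	N	-0.10	3.25	0.170
LYS	CA	0.10	3.75	0.105
LYS	C	0.45	3.75	0.105
LYS	O	-0.45	2.96	0.210
LYS	CB	0.00	3.75	0.105
LYS	CG	0.00	3.75	0.105
LYS	CD	0.00	3.75	0.105
LYS	CE	0.25	3.75	0.105
LYS	NZ	0.75	3.25	0.170
LYS	OXT	-0.45	2.96	0.210
MET	N	-0.10	3.25	0.170
MET	CA	0.10	3.75	0.105
MET	C	0.45	3.75	0.105
MET	O	-0.45	2.96	0.210
MET	CB	0.05	3.75	0.105
MET	CG	0.05	3.75	0.105
MET	SD	-0.10	3.55	0.250
MET	CE	0.00	3.75	0.105
MET	OXT	-0.45	2.96	0.210
PHE	N	-0.10	3.25	0.170
PHE	CA	0.10	3.75	0.105
PHE	C	0.45	3.75	0.105
PHE	O	-0.45	2.96	0.210
PHE	CB	0.00	3.75	0.105
PHE	CG	0.00	3.75	0.105
PHE	CD1	0.00	3.75	0.105
PHE	CD2	0.00	3.75	0.105
PHE	CE1	0.00	3.75	0.105
PHE	CE2	0.00	3.75	0.105
PHE	CZ	0.00	3.75	0.105
PHE	OXT	-0.45	2.96	0.210
PRO	N	-0.10	3.25	0.170
PRO	CA	0.10	3.75	0.105
PRO	C	0.45	3.75	0.105
PRO	O	-0.45	2.96	0.210
PRO	CB	0.00	3.75	0.105
PRO	CG	0.00	3.75	0.105
PRO	CD	0.10	3.75	0.105
PRO	OXT	-0.45	2.96	0.210
SER	N	-0.10	3.25	0.170
SER	CA	0.10	3.75	0.105
SER	C	0.45	3.75	0.105
SER	O	-0.45	2.96	0.210
SER	CB	0.25	3.75	0.105
SER	OG	-0.25	2.96	0.210
SER	OXT	-0.45	2.96	0.210
THR	N	-0.10	3.25	0.170
THR	CA	0.10	3.75	0.105
THR	C	0.45	3.75	0.105
THR	O	-0.45	2.96	0.210
THR	CB	0.25	3.75	0.105
THR	OG1	-0.25	2.96	0.210
THR	CG2	0.00	3.75	0.105
THR	OXT	-0.45	2.96	0.210
TRP	N	-0.10	3.25	0.170
TRP	CA	0.10	3.75	0.105
TRP	C	0.45	3.75	0.105
TRP	O	-0.45	2.96	0.210
TRP	CB	0.00	3.75	0.105
TRP	CG	0.00	3.75	0.105
TRP	CD1	0.10	3.75	0.105
TRP	CD2	0.00	3.75	0.105
TRP	NE1	-0.20	3.25	0.170
TRP	CE2	0.10	3.75	0.105
TRP	CE3	0.00	3.75	0.105
TRP	CZ2	0.00	3.75	0.105
TRP	CZ3	0.00	3.75	0.105
TRP	CH2	0.00	3.75	0.105
TRP	OXT	-0.45	2.96	0.210
TYR	N	-0.10	3.25	0.170
TYR	CA	0.10	3.75	0.105
TYR	C	0.45	3.75	0.105
TYR	O	-0.45	2.96	0.210
TYR	CB	0.00	3.75	0.105
TYR	CG	0.00	3.75	0.105
TYR	CD1	0.00	3.75	0.105
TYR	CD2	0.00	3.75	0.105
TYR	CE1	0.00	3.75	0.105
TYR	CE2	0.00	3.75	0.105
TYR	CZ	0.25	3.75	0.105
TYR	OH	-0.25	2.96	0.210
TYR	OXT	-0.45	2.96	0.210
VAL	N	-0.10	3.25	0.170
VAL	CA	0.10	3.75	0.105
VAL	C	0.45	3.75	0.105
VAL	O	-0.45	2.96	0.210
VAL	CB	0.00	3.75	0.105
VAL	CG1	0.00	3.75	0.105
VAL	CG2	0.00	3.75	0.105
VAL	OXT	-0.45	2.96	0.210
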