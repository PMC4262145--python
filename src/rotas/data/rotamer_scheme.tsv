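# Rotamer scheme: governing side-chain dihedrals and state counts
# per residue-specific heavy atom type (167 rows).
# residue	atom	dihedrals	states
ALA	N	-	1
ALA	CA	-	1
ALA	C	-	1
ALA	O	-	1
ALA	CB	-	1
ARG	N	chi1,chi2	9
ARG	CA	chi1,chi2	9
ARG	C	chi1,chi2	9
ARG	O	chi1,chi2	9
ARG	CB	chi1,chi2	9
ARG	CG	chi2,chi3	9
ARG	CD	chi3,chi4	9
ARG	NE	chi3,chi4	9
ARG	CZ	chi3,chi4	9
ARG	NH1	chi4	3
ARG	NH2	chi4	3
ASN	N	chi1,chi2	6
ASN	CA	chi1,chi2	6
ASN	C	chi1,chi2	6
ASN	O	chi1,chi2	6
ASN	CB	chi1,chi2	6
ASN	CG	chi1,chi2	6
ASN	OD1	chi1,chi2	6
ASN	ND2	chi1,chi2	6
ASP	N	chi1,chi2	6
ASP	CA	chi1,chi2	6
ASP	C	chi1,chi2	6
ASP	O	chi1,chi2	6
ASP	CB	chi1,chi2	6
ASP	CG	chi1,chi2	6
ASP	OD1	chi1,chi2	6
ASP	OD2	chi1,chi2	6
CYS	N	chi1	3
CYS	CA	chi1	3
CYS	C	chi1	3
CYS	O	chi1	3
CYS	CB	chi1	3
CYS	SG	chi1	3
GLN	N	chi1,chi2	9
GLN	CA	chi1,chi2	9
GLN	C	chi1,chi2	9
GLN	O	chi1,chi2	9
GLN	CB	chi1,chi2	9
GLN	CG	chi2,chi3	6
GLN	CD	chi2,chi3	6
GLN	OE1	chi2,chi3	6
GLN	NE2	chi2,chi3	6
GLU	N	chi1,chi2	9
GLU	CA	chi1,chi2	9
GLU	C	chi1,chi2	9
GLU	O	chi1,chi2	9
GLU	CB	chi1,chi2	9
GLU	CG	chi1,chi2	9
GLU	CD	chi2,chi3	6
GLU	OE1	chi2,chi3	6
GLU	OE2	chi2,chi3	6
GLY	N	-	1
GLY	CA	-	1
GLY	C	-	1
GLY	O	-	1
HIS	N	chi1,chi2	6
HIS	CA	chi1,chi2	6
HIS	C	chi1,chi2	6
HIS	O	chi1,chi2	6
HIS	CB	chi1,chi2	6
HIS	CG	chi1,chi2	6
HIS	ND1	chi1,chi2	6
HIS	CD2	chi1,chi2	6
HIS	CE1	chi2	2
HIS	NE2	chi2	2
ILE	N	chi1,chi2	9
ILE	CA	chi1,chi2	9
ILE	C	chi1,chi2	9
ILE	O	chi1,chi2	9
ILE	CB	chi1,chi2	9
ILE	CG1	chi1,chi2	9
ILE	CG2	chi1,chi2	9
ILE	CD1	chi1,chi2	9
LEU	N	chi1,chi2	9
LEU	CA	chi1,chi2	9
LEU	C	chi1,chi2	9
LEU	O	chi1,chi2	9
LEU	CB	chi1,chi2	9
LEU	CG	chi1,chi2	9
LEU	CD1	chi1,chi2	9
LEU	CD2	chi1,chi2	9
LYS	N	chi1,chi2	9
LYS	CA	chi1,chi2	9
LYS	C	chi1,chi2	9
LYS	O	chi1,chi2	9
LYS	CB	chi1,chi2	9
LYS	CG	chi2,chi3	9
LYS	CD	chi3,chi4	9
LYS	CE	chi3,chi4	9
LYS	NZ	chi3,chi4	9
MET	N	chi1,chi2	9
MET	CA	chi1,chi2	9
MET	C	chi1,chi2	9
MET	O	chi1,chi2	9
MET	CB	chi1,chi2	9
MET	CG	chi2,chi3	9
MET	SD	chi2,chi3	9
MET	CE	chi2,chi3	9
PHE	N	chi1	3
PHE	CA	chi1	3
PHE	C	chi1	3
PHE	O	chi1	3
PHE	CB	chi1	3
PHE	CG	chi1,chi2	6
PHE	CD1	chi1,chi2	6
PHE	CD2	chi1,chi2	6
PHE	CE1	chi2	2
PHE	CE2	chi2	2
PHE	CZ	chi2	2
PRO	N	chi1	3
PRO	CA	chi1	3
PRO	C	chi1	3
PRO	O	chi1	3
PRO	CB	chi1	3
PRO	CG	chi1	3
PRO	CD	chi1	3
SER	N	chi1	3
SER	CA	chi1	3
SER	C	chi1	3
SER	O	chi1	3
SER	CB	chi1	3
SER	OG	chi1	3
THR	N	chi1	3
THR	CA	chi1	3
THR	C	chi1	3
THR	O	chi1	3
THR	CB	chi1	3
THR	OG1	chi1	3
THR	CG2	chi1	3
TRP	N	chi1,chi2	6
TRP	CA	chi1,chi2	6
TRP	C	chi1,chi2	6
TRP	O	chi1,chi2	6
TRP	CB	chi1,chi2	6
TRP	CG	chi1,chi2	6
TRP	CD1	chi1,chi2	6
TRP	CD2	chi1,chi2	6
TRP	NE1	chi2	2
TRP	CE2	chi2	2
TRP	CE3	chi2	2
TRP	CZ2	chi2	2
TRP	CZ3	chi2	2
TRP	CH2	chi2	2
TYR	N	chi1	3
TYR	CA	chi1	3
TYR	C	chi1	3
TYR	O	chi1	3
TYR	CB	chi1	3
TYR	CG	chi1,chi2	6
TYR	CD1	chi1,chi2	6
TYR	CD2	chi1,chi2	6
TYR	CE1	chi2	2
TYR	CE2	chi2	2
TYR	CZ	chi2	2
TYR	OH	chi2	2
VAL	N	chi1	3
VAL	CA	chi1	3
VAL	C	chi1	3
VAL	O	chi1	3
VAL	CB	chi1	3
VAL	CG1	chi1	3
VAL	CG2	chi1	3
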