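# Simplified OPLS-like non-bonded parameters: heavy atoms and polar
# hydrogens of the 20 amino acids.  Charges are united-atom style
# (nonpolar hydrogens folded into carbons) and sum to each residue's
# formal charge.  sigma in nm, epsilon in kJ/mol, charge in e.
residue_name	atom_name	charge_e	sigma_nm	epsilon_kJmol
ALA	N	-0.5700	0.325	0.711
ALA	H	0.3700	0.100	0.000
ALA	CA	0.2000	0.350	0.276
ALA	C	0.5000	0.375	0.439
ALA	O	-0.5000	0.296	0.879
ALA	CB	0.0000	0.350	0.276
ARG	N	-0.5700	0.325	0.711
ARG	H	0.3700	0.100	0.000
ARG	CA	0.2000	0.350	0.276
ARG	C	0.5000	0.375	0.439
ARG	O	-0.5000	0.296	0.879
ARG	CB	0.0000	0.350	0.276
ARG	CG	0.0000	0.350	0.276
ARG	CD	0.1900	0.350	0.276
ARG	NE	-0.7000	0.325	0.711
ARG	HE	0.4400	0.100	0.000
ARG	CZ	0.6400	0.375	0.439
ARG	NH1	-0.8000	0.325	0.711
ARG	NH2	-0.8000	0.325	0.711
ARG	HH11	0.5075	0.100	0.000
ARG	HH12	0.5075	0.100	0.000
ARG	HH21	0.5075	0.100	0.000
ARG	HH22	0.5075	0.100	0.000
ASN	N	-0.5700	0.325	0.711
ASN	H	0.3700	0.100	0.000
ASN	CA	0.2000	0.350	0.276
ASN	C	0.5000	0.375	0.439
ASN	O	-0.5000	0.296	0.879
ASN	CB	0.0000	0.350	0.276
ASN	CG	0.5000	0.375	0.439
ASN	OD1	-0.5000	0.296	0.879
ASN	ND2	-0.8500	0.325	0.711
ASN	HD21	0.4250	0.100	0.000
ASN	HD22	0.4250	0.100	0.000
ASP	N	-0.5700	0.325	0.711
ASP	H	0.3700	0.100	0.000
ASP	CA	0.2000	0.350	0.276
ASP	C	0.5000	0.375	0.439
ASP	O	-0.5000	0.296	0.879
ASP	CB	-0.1000	0.350	0.276
ASP	CG	0.7000	0.375	0.439
ASP	OD1	-0.8000	0.296	0.879
ASP	OD2	-0.8000	0.296	0.879
CYS	N	-0.5700	0.325	0.711
CYS	H	0.3700	0.100	0.000
CYS	CA	0.2000	0.350	0.276
CYS	C	0.5000	0.375	0.439
CYS	O	-0.5000	0.296	0.879
CYS	CB	0.1800	0.350	0.276
CYS	SG	-0.4500	0.355	1.046
CYS	HG	0.2700	0.100	0.000
GLN	N	-0.5700	0.325	0.711
GLN	H	0.3700	0.100	0.000
GLN	CA	0.2000	0.350	0.276
GLN	C	0.5000	0.375	0.439
GLN	O	-0.5000	0.296	0.879
GLN	CB	0.0000	0.350	0.276
GLN	CG	0.0000	0.350	0.276
GLN	CD	0.5000	0.375	0.439
GLN	OE1	-0.5000	0.296	0.879
GLN	NE2	-0.8500	0.325	0.711
GLN	HE21	0.4250	0.100	0.000
GLN	HE22	0.4250	0.100	0.000
GLU	N	-0.5700	0.325	0.711
GLU	H	0.3700	0.100	0.000
GLU	CA	0.2000	0.350	0.276
GLU	C	0.5000	0.375	0.439
GLU	O	-0.5000	0.296	0.879
GLU	CB	0.0000	0.350	0.276
GLU	CG	-0.1000	0.350	0.276
GLU	CD	0.7000	0.375	0.439
GLU	OE1	-0.8000	0.296	0.879
GLU	OE2	-0.8000	0.296	0.879
GLY	N	-0.5700	0.325	0.711
GLY	H	0.3700	0.100	0.000
GLY	CA	0.2000	0.350	0.276
GLY	C	0.5000	0.375	0.439
GLY	O	-0.5000	0.296	0.879
HIS	N	-0.5700	0.325	0.711
HIS	H	0.3700	0.100	0.000
HIS	CA	0.2000	0.350	0.276
HIS	C	0.5000	0.375	0.439
HIS	O	-0.5000	0.296	0.879
HIS	CB	0.0000	0.350	0.276
HIS	CG	0.1500	0.355	0.293
HIS	ND1	-0.5700	0.325	0.711
HIS	HD1	0.4200	0.100	0.000
HIS	CD2	0.1000	0.355	0.293
HIS	CE1	0.3000	0.355	0.293
HIS	NE2	-0.4000	0.325	0.711
ILE	N	-0.5700	0.325	0.711
ILE	H	0.3700	0.100	0.000
ILE	CA	0.2000	0.350	0.276
ILE	C	0.5000	0.375	0.439
ILE	O	-0.5000	0.296	0.879
ILE	CB	0.0000	0.350	0.276
ILE	CG1	0.0000	0.350	0.276
ILE	CG2	0.0000	0.350	0.276
ILE	CD1	0.0000	0.350	0.276
LEU	N	-0.5700	0.325	0.711
LEU	H	0.3700	0.100	0.000
LEU	CA	0.2000	0.350	0.276
LEU	C	0.5000	0.375	0.439
LEU	O	-0.5000	0.296	0.879
LEU	CB	0.0000	0.350	0.276
LEU	CG	0.0000	0.350	0.276
LEU	CD1	0.0000	0.350	0.276
LEU	CD2	0.0000	0.350	0.276
LYS	N	-0.5700	0.325	0.711
LYS	H	0.3700	0.100	0.000
LYS	CA	0.2000	0.350	0.276
LYS	C	0.5000	0.375	0.439
LYS	O	-0.5000	0.296	0.879
LYS	CB	0.0000	0.350	0.276
LYS	CG	0.0000	0.350	0.276
LYS	CD	0.0000	0.350	0.276
LYS	CE	0.3100	0.350	0.276
LYS	NZ	-0.3000	0.325	0.711
LYS	HZ1	0.3300	0.100	0.000
LYS	HZ2	0.3300	0.100	0.000
LYS	HZ3	0.3300	0.100	0.000
MET	N	-0.5700	0.325	0.711
MET	H	0.3700	0.100	0.000
MET	CA	0.2000	0.350	0.276
MET	C	0.5000	0.375	0.439
MET	O	-0.5000	0.296	0.879
MET	CB	0.0000	0.350	0.276
MET	CG	0.2350	0.350	0.276
MET	SD	-0.4700	0.355	1.046
MET	CE	0.2350	0.350	0.276
PHE	N	-0.5700	0.325	0.711
PHE	H	0.3700	0.100	0.000
PHE	CA	0.2000	0.350	0.276
PHE	C	0.5000	0.375	0.439
PHE	O	-0.5000	0.296	0.879
PHE	CB	0.0000	0.350	0.276
PHE	CG	0.0000	0.355	0.293
PHE	CD1	0.0000	0.355	0.293
PHE	CD2	0.0000	0.355	0.293
PHE	CE1	0.0000	0.355	0.293
PHE	CE2	0.0000	0.355	0.293
PHE	CZ	0.0000	0.355	0.293
PRO	N	-0.2000	0.325	0.711
PRO	CA	0.2000	0.350	0.276
PRO	C	0.5000	0.375	0.439
PRO	O	-0.5000	0.296	0.879
PRO	CB	0.0000	0.350	0.276
PRO	CG	0.0000	0.350	0.276
PRO	CD	0.0000	0.350	0.276
SER	N	-0.5700	0.325	0.711
SER	H	0.3700	0.100	0.000
SER	CA	0.2000	0.350	0.276
SER	C	0.5000	0.375	0.439
SER	O	-0.5000	0.296	0.879
SER	CB	0.2650	0.350	0.276
SER	OG	-0.7000	0.312	0.711
SER	HG	0.4350	0.100	0.000
THR	N	-0.5700	0.325	0.711
THR	H	0.3700	0.100	0.000
THR	CA	0.2000	0.350	0.276
THR	C	0.5000	0.375	0.439
THR	O	-0.5000	0.296	0.879
THR	CB	0.2650	0.350	0.276
THR	OG1	-0.7000	0.312	0.711
THR	HG1	0.4350	0.100	0.000
THR	CG2	0.0000	0.350	0.276
TRP	N	-0.5700	0.325	0.711
TRP	H	0.3700	0.100	0.000
TRP	CA	0.2000	0.350	0.276
TRP	C	0.5000	0.375	0.439
TRP	O	-0.5000	0.296	0.879
TRP	CB	0.0000	0.350	0.276
TRP	CG	0.0000	0.355	0.293
TRP	CD1	0.0600	0.355	0.293
TRP	CD2	0.0000	0.355	0.293
TRP	NE1	-0.5700	0.325	0.711
TRP	HE1	0.4200	0.100	0.000
TRP	CE2	0.0900	0.355	0.293
TRP	CE3	0.0000	0.355	0.293
TRP	CZ2	0.0000	0.355	0.293
TRP	CZ3	0.0000	0.355	0.293
TRP	CH2	0.0000	0.355	0.293
TYR	N	-0.5700	0.325	0.711
TYR	H	0.3700	0.100	0.000
TYR	CA	0.2000	0.350	0.276
TYR	C	0.5000	0.375	0.439
TYR	O	-0.5000	0.296	0.879
TYR	CB	0.0000	0.350	0.276
TYR	CG	0.0000	0.355	0.293
TYR	CD1	0.0000	0.355	0.293
TYR	CD2	0.0000	0.355	0.293
TYR	CE1	0.0000	0.355	0.293
TYR	CE2	0.0000	0.355	0.293
TYR	CZ	0.2650	0.355	0.293
TYR	OH	-0.7000	0.312	0.711
TYR	HH	0.4350	0.100	0.000
VAL	N	-0.5700	0.325	0.711
VAL	H	0.3700	0.100	0.000
VAL	CA	0.2000	0.350	0.276
VAL	C	0.5000	0.375	0.439
VAL	O	-0.5000	0.296	0.879
VAL	CB	0.0000	0.350	0.276
VAL	CG1	0.0000	0.350	0.276
VAL	CG2	0.0000	0.350	0.276
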