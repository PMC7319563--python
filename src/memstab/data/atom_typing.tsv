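# Pharmacophore atom typing for the 20 standard residues (heavy atoms only).
# Columns: residue aa3, PDB atom name, comma-separated class labels.
# Classes: hydrophobic, positive, negative, hbond_acceptor, hbond_donor,
#          aromatic, sulfur, neutral.
# Conventions: hydrogens are absent from typical PDB files, so donors are
# identified by their heavy-atom carrier; histidine follows the pH-7 neutral
# tautomer convention (aromatic donor/acceptor nitrogens, no formal charge);
# proline's backbone nitrogen has no amide proton and carries no donor class.
ALA	N	hbond_donor
ALA	CA	hydrophobic
ALA	C	neutral
ALA	O	hbond_acceptor
ALA	CB	hydrophobic
ARG	N	hbond_donor
ARG	CA	hydrophobic
ARG	C	neutral
ARG	O	hbond_acceptor
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	neutral
ARG	NE	positive,hbond_donor
ARG	CZ	neutral
ARG	NH1	positive,hbond_donor
ARG	NH2	positive,hbond_donor
ASN	N	hbond_donor
ASN	CA	hydrophobic
ASN	C	neutral
ASN	O	hbond_acceptor
ASN	CB	hydrophobic
ASN	CG	neutral
ASN	OD1	hbond_acceptor
ASN	ND2	hbond_donor
ASP	N	hbond_donor
ASP	CA	hydrophobic
ASP	C	neutral
ASP	O	hbond_acceptor
ASP	CB	hydrophobic
ASP	CG	neutral
ASP	OD1	negative,hbond_acceptor
ASP	OD2	negative,hbond_acceptor
CYS	N	hbond_donor
CYS	CA	hydrophobic
CYS	C	neutral
CYS	O	hbond_acceptor
CYS	CB	hydrophobic
CYS	SG	sulfur
GLN	N	hbond_donor
GLN	CA	hydrophobic
GLN	C	neutral
GLN	O	hbond_acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	neutral
GLN	OE1	hbond_acceptor
GLN	NE2	hbond_donor
GLU	N	hbond_donor
GLU	CA	hydrophobic
GLU	C	neutral
GLU	O	hbond_acceptor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	neutral
GLU	OE1	negative,hbond_acceptor
GLU	OE2	negative,hbond_acceptor
GLY	N	hbond_donor
GLY	CA	hydrophobic
GLY	C	neutral
GLY	O	hbond_acceptor
HIS	N	hbond_donor
HIS	CA	hydrophobic
HIS	C	neutral
HIS	O	hbond_acceptor
HIS	CB	hydrophobic
HIS	CG	aromatic,hydrophobic
HIS	ND1	aromatic,hbond_donor,hbond_acceptor
HIS	CD2	aromatic,hydrophobic
HIS	CE1	aromatic,hydrophobic
HIS	NE2	aromatic,hbond_donor,hbond_acceptor
ILE	N	hbond_donor
ILE	CA	hydrophobic
ILE	C	neutral
ILE	O	hbond_acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
LEU	N	hbond_donor
LEU	CA	hydrophobic
LEU	C	neutral
LEU	O	hbond_acceptor
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LYS	N	hbond_donor
LYS	CA	hydrophobic
LYS	C	neutral
LYS	O	hbond_acceptor
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	neutral
LYS	NZ	positive,hbond_donor
MET	N	hbond_donor
MET	CA	hydrophobic
MET	C	neutral
MET	O	hbond_acceptor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	sulfur
MET	CE	hydrophobic
PHE	N	hbond_donor
PHE	CA	hydrophobic
PHE	C	neutral
PHE	O	hbond_acceptor
PHE	CB	hydrophobic
PHE	CG	aromatic,hydrophobic
PHE	CD1	aromatic,hydrophobic
PHE	CD2	aromatic,hydrophobic
PHE	CE1	aromatic,hydrophobic
PHE	CE2	aromatic,hydrophobic
PHE	CZ	aromatic,hydrophobic
PRO	N	neutral
PRO	CA	hydrophobic
PRO	C	neutral
PRO	O	hbond_acceptor
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	hydrophobic
SER	N	hbond_donor
SER	CA	hydrophobic
SER	C	neutral
SER	O	hbond_acceptor
SER	CB	neutral
SER	OG	hbond_donor,hbond_acceptor
THR	N	hbond_donor
THR	CA	hydrophobic
THR	C	neutral
THR	O	hbond_acceptor
THR	CB	neutral
THR	OG1	hbond_donor,hbond_acceptor
THR	CG2	hydrophobic
TRP	N	hbond_donor
TRP	CA	hydrophobic
TRP	C	neutral
TRP	O	hbond_acceptor
TRP	CB	hydrophobic
TRP	CG	aromatic,hydrophobic
TRP	CD1	aromatic,hydrophobic
TRP	CD2	aromatic,hydrophobic
TRP	NE1	aromatic,hbond_donor
TRP	CE2	aromatic,hydrophobic
TRP	CE3	aromatic,hydrophobic
TRP	CZ2	aromatic,hydrophobic
TRP	CZ3	aromatic,hydrophobic
TRP	CH2	aromatic,hydrophobic
TYR	N	hbond_donor
TYR	CA	hydrophobic
TYR	C	neutral
TYR	O	hbond_acceptor
TYR	CB	hydrophobic
TYR	CG	aromatic,hydrophobic
TYR	CD1	aromatic,hydrophobic
TYR	CD2	aromatic,hydrophobic
TYR	CE1	aromatic,hydrophobic
TYR	CE2	aromatic,hydrophobic
TYR	CZ	aromatic,hydrophobic
TYR	OH	hbond_donor,hbond_acceptor
VAL	N	hbond_donor
VAL	CA	hydrophobic
VAL	C	neutral
VAL	O	hbond_acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
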