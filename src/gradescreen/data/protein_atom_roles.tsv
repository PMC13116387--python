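# Simplified pharmacophore roles for standard amino-acid atoms (heavy atoms only).
# roles: comma-separated subset of donor,acceptor,cation,anion,hydrophobic,ring
# Backbone: N is a donor (except PRO), O an acceptor; C/CA/CB handling is per residue.
# Aromatic ring atoms carry only the ring role here; one ring per residue
# (the six-membered ring for TRP).
resname	atom_name	roles
*	N	donor
*	O	acceptor
*	OXT	acceptor,anion
PRO	N
ALA	CB	hydrophobic
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	CE	hydrophobic
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	hydrophobic
PHE	CB	hydrophobic
PHE	CG	ring
PHE	CD1	ring
PHE	CD2	ring
PHE	CE1	ring
PHE	CE2	ring
PHE	CZ	ring
TYR	CB	hydrophobic
TYR	CG	ring
TYR	CD1	ring
TYR	CD2	ring
TYR	CE1	ring
TYR	CE2	ring
TYR	CZ	ring
TYR	OH	donor,acceptor
TRP	CB	hydrophobic
TRP	NE1	donor
TRP	CD2	ring
TRP	CE2	ring
TRP	CE3	ring
TRP	CZ2	ring
TRP	CZ3	ring
TRP	CH2	ring
HIS	CG	ring
HIS	ND1	donor,acceptor,ring
HIS	CD2	ring
HIS	CE1	ring
HIS	NE2	donor,acceptor,ring
SER	OG	donor,acceptor
THR	OG1	donor,acceptor
THR	CG2	hydrophobic
CYS	CB	hydrophobic
ASN	CB	hydrophobic
ASN	OD1	acceptor
ASN	ND2	donor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	OE1	acceptor
GLN	NE2	donor
ASP	CB	hydrophobic
ASP	OD1	acceptor,anion
ASP	OD2	acceptor,anion
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	OE1	acceptor,anion
GLU	OE2	acceptor,anion
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	NZ	donor,cation
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	NE	donor,cation
ARG	NH1	donor,cation
ARG	NH2	donor,cation
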