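# Amino-acid residues (peptide-bond form, i.e. free amino acid minus one water).
# n_labile counts solvent-exchangeable hydrogens including the backbone amide,
# with charged side chains in their pH-7 protonation states (Lys-NH3+, Arg-guanidinium,
# ionized Asp/Glu carboxylates).
# Volumes in Å³: 'zamyatnin1984' (canonical) and 'jacrot1976' (alternate).
# code	name	formula	n_labile	vol_zamyatnin1984	vol_jacrot1976
G	GLY	C2H3NO	1	60.1	66.4
A	ALA	C3H5NO	1	88.6	91.5
S	SER	C3H5NO2	2	89.0	99.1
C	CYS	C3H5NOS	2	108.5	105.6
D	ASP	C4H5NO3	1	111.1	113.6
P	PRO	C5H7NO	0	112.7	129.3
N	ASN	C4H6N2O2	3	114.1	135.2
T	THR	C4H7NO2	2	116.1	122.1
E	GLU	C5H7NO4	1	138.4	140.6
V	VAL	C5H9NO	1	140.0	141.7
Q	GLN	C5H8N2O2	3	143.8	161.1
H	HIS	C6H7N3O	2	153.2	167.3
M	MET	C5H9NOS	1	162.9	170.8
I	ILE	C6H11NO	1	166.7	168.8
L	LEU	C6H11NO	1	166.7	167.9
K	LYS	C6H12N2O	4	168.6	176.2
R	ARG	C6H12N4O	6	173.4	180.8
F	PHE	C9H9NO	1	189.9	203.4
Y	TYR	C9H9NO2	2	193.6	203.6
W	TRP	C11H10N2O	2	227.8	237.6
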