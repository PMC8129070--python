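# chromocg residue parameter table, version 1.0
# diameter [A]: from van der Waals volumes assuming spherical beads
# charge [e]: at neutral pH; histidine defaults to 0 (config-switchable)
# mass [g/mol]: average residue mass
# contact_h [dimensionless]: one-body contact-propensity factor; the pair
#   contact energy is built additively as e_ij = -(h_i + h_j)
code	name	mass	charge	diameter	contact_h
A	ALA	71.08	0	5.04	1.30
R	ARG	156.19	1	6.56	1.00
N	ASN	114.10	0	5.68	0.80
D	ASP	115.09	-1	5.58	0.60
C	CYS	103.14	0	5.48	2.70
Q	GLN	128.13	0	6.02	0.90
E	GLU	129.12	-1	5.92	0.60
G	GLY	57.05	0	4.50	1.10
H	HIS	137.14	0	6.08	1.40
I	ILE	113.16	0	6.18	3.20
L	LEU	113.16	0	6.18	3.50
K	LYS	128.17	1	6.36	0.60
M	MET	131.20	0	6.18	2.90
F	PHE	147.18	0	6.36	3.60
P	PRO	97.12	0	5.56	1.30
S	SER	87.08	0	5.18	0.90
T	THR	101.10	0	5.62	1.20
V	VAL	99.07	0	5.86	2.90
W	TRP	186.21	0	6.78	3.20
Y	TYR	163.18	0	6.46	2.40
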