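residue_name	atom	rc_ppm	helix_full_ppm	strand_full_ppm
ALA	CA	52.5	3.1	-1.5
ALA	CB	19.1	-0.38	2.16
ALA	HA	4.32	-0.39	0.37
ARG	CA	56.0	3.1	-1.5
ARG	CB	30.9	-0.38	2.16
ARG	HA	4.34	-0.39	0.37
ASN	CA	52.8	3.1	-1.5
ASN	CB	38.9	-0.38	2.16
ASN	HA	4.74	-0.39	0.37
ASP	CA	54.2	3.1	-1.5
ASP	CB	41.1	-0.38	2.16
ASP	HA	4.64	-0.39	0.37
CYS	CA	58.2	3.1	-1.5
CYS	CB	28.0	-0.38	2.16
CYS	HA	4.71	-0.39	0.37
GLN	CA	55.7	3.1	-1.5
GLN	CB	29.4	-0.38	2.16
GLN	HA	4.34	-0.39	0.37
GLU	CA	56.6	3.1	-1.5
GLU	CB	29.9	-0.38	2.16
GLU	HA	4.35	-0.39	0.37
GLY	CA	45.1	3.1	-1.5
GLY	HA	3.96	-0.39	0.37
HIS	CA	55.0	3.1	-1.5
HIS	CB	29.0	-0.38	2.16
HIS	HA	4.73	-0.39	0.37
ILE	CA	61.1	3.1	-1.5
ILE	CB	38.8	-0.38	2.16
ILE	HA	4.17	-0.39	0.37
LEU	CA	55.1	3.1	-1.5
LEU	CB	42.4	-0.38	2.16
LEU	HA	4.34	-0.39	0.37
LYS	CA	56.2	3.1	-1.5
LYS	CB	33.1	-0.38	2.16
LYS	HA	4.32	-0.39	0.37
MET	CA	55.4	3.1	-1.5
MET	CB	32.9	-0.38	2.16
MET	HA	4.48	-0.39	0.37
PHE	CA	57.7	3.1	-1.5
PHE	CB	39.6	-0.38	2.16
PHE	HA	4.62	-0.39	0.37
PRO	CA	63.3	3.1	-1.5
PRO	CB	32.1	-0.38	2.16
PRO	HA	4.42	-0.39	0.37
SER	CA	58.3	3.1	-1.5
SER	CB	63.8	-0.38	2.16
SER	HA	4.47	-0.39	0.37
THR	CA	61.8	3.1	-1.5
THR	CB	69.8	-0.38	2.16
THR	HA	4.35	-0.39	0.37
TRP	CA	57.5	3.1	-1.5
TRP	CB	29.8	-0.38	2.16
TRP	HA	4.66	-0.39	0.37
TYR	CA	57.9	3.1	-1.5
TYR	CB	38.8	-0.38	2.16
TYR	HA	4.55	-0.39	0.37
VAL	CA	62.2	3.1	-1.5
VAL	CB	32.9	-0.38	2.16
VAL	HA	4.12	-0.39	0.37
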