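residue_name	j_coil_hz
ALA	6.6
ARG	7.2
ASN	7.3
ASP	7.1
CYS	7.3
GLN	7.1
GLU	7.0
GLY	6.9
HIS	7.2
ILE	7.6
LEU	7.1
LYS	7.1
MET	7.2
PHE	7.4
PRO	7.2
SER	7.0
THR	7.6
TRP	7.2
TYR	7.4
VAL	7.5
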