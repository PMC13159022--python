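# Per-residue physicochemical properties for the 20 canonical amino acids.
# h_kd: Kyte-Doolittle hydropathy (AAindex KYTJ820101), dimensionless.
# pi:   residue isoelectric point (AAindex ZIMJ680104, Zimmerman 1968), pH units.
# vdw:  van der Waals volume (Darby & Creighton 1993), cubic Angstrom.
aa	h_kd	pi	vdw
A	1.8	6.00	67
C	2.5	5.05	86
D	-3.5	2.77	91
E	-3.5	3.22	109
F	2.8	5.48	135
G	-0.4	5.97	48
H	-3.2	7.59	118
I	4.5	6.02	124
K	-3.9	9.74	135
L	3.8	5.98	124
M	1.9	5.74	124
N	-3.5	5.41	96
P	-1.6	6.30	90
Q	-3.5	5.65	114
R	-4.5	10.76	148
S	-0.8	5.68	73
T	-0.7	5.66	93
V	4.2	5.96	105
W	-0.9	5.89	163
Y	-1.3	5.66	141
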