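# name: bull_breese
# source: Bull & Breese (1974) Arch Biochem Biophys 161:665-670, surface free energy of transfer (kcal/mol x 1e-2)
# alphabet: protein
A	0.61
R	0.69
N	0.89
D	0.61
C	0.36
Q	0.97
E	0.51
G	0.81
H	0.69
I	-1.45
L	-1.65
K	0.46
M	-0.66
F	-1.52
P	-0.35
S	0.42
T	0.29
W	-1.20
Y	-1.43
V	-0.75
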