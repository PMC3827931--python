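# name: chou_fasman_turn
# source: Chou & Fasman (1978) Adv Enzymol 47:45-148, beta-turn conformational propensity P(t)
# alphabet: protein
A	0.66
R	0.95
N	1.56
D	1.46
C	1.19
Q	0.98
E	0.74
G	1.56
H	0.95
I	0.47
L	0.59
K	1.01
M	0.60
F	0.60
P	1.52
S	1.43
T	0.96
W	0.96
Y	1.14
V	0.50
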