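# scale: residue van der Waals volume (A^3)
# source: Darby & Creighton (1993), Protein Structure, standard residue volume set
residue,value
A,67
R,148
N,96
D,91
C,86
E,109
Q,114
G,48
H,118
I,124
L,124
K,135
M,124
F,135
P,90
S,73
T,93
W,163
Y,141
V,105
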