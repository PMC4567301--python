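# scale: aromatic side-chain indicator (1 = Phe/Trp/Tyr, 0 otherwise)
# His is treated as non-aromatic by default; override the table to include it
residue,value
A,0
R,0
N,0
D,0
C,0
E,0
Q,0
G,0
H,0
I,0
L,0
K,0
M,0
F,1
P,0
S,0
T,0
W,1
Y,1
V,0
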