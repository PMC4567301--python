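# scale: accessible surface area of residue X in an extended Ala-X-Ala tripeptide (A^2)
# ECEPP/2 extended-state reference values; used both as the SASA property scale and
# as the denominator that converts raw ASA to percentage exposure
residue,value
A,110.2
D,144.1
C,140.4
E,174.7
F,200.7
G,78.7
H,181.9
I,185.0
K,205.7
L,183.1
M,200.1
N,146.4
P,141.9
Q,178.6
R,229.0
S,117.2
T,138.7
V,153.7
W,240.5
Y,213.7
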