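# side-chain centroid radii v1 (Angstrom)
aa,radius
A,1.7
C,2.0
D,2.4
E,2.7
F,3.0
G,1.0
H,2.8
I,2.6
K,2.9
L,2.6
M,2.8
N,2.4
P,2.2
Q,2.7
R,3.2
S,1.9
T,2.1
V,2.3
W,3.4
Y,3.1
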