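# P(amino acid | backbone dihedral bin) v1, columns sum to 1
,alphaR,beta,alphaL,ppii,other
A,0.09016,0.03534,0.02516,0.04301,0.04167
C,0.02869,0.08481,0.02516,0.04301,0.04167
D,0.04098,0.03534,0.12579,0.04301,0.04167
E,0.09016,0.03534,0.02516,0.04301,0.04167
F,0.02869,0.08481,0.02516,0.04301,0.04167
G,0.01639,0.01060,0.31447,0.04301,0.16667
H,0.04098,0.03534,0.02516,0.04301,0.04167
I,0.02869,0.08481,0.02516,0.04301,0.04167
K,0.09016,0.03534,0.02516,0.04301,0.04167
L,0.09016,0.03534,0.02516,0.04301,0.04167
M,0.09016,0.03534,0.02516,0.04301,0.04167
N,0.04098,0.03534,0.15094,0.04301,0.04167
P,0.01230,0.00707,0.00629,0.16129,0.08333
Q,0.09016,0.03534,0.02516,0.04301,0.04167
R,0.06557,0.03534,0.02516,0.04301,0.04167
S,0.04098,0.03534,0.02516,0.06452,0.04167
T,0.02869,0.08481,0.02516,0.04301,0.04167
V,0.02869,0.08481,0.02516,0.04301,0.04167
W,0.02869,0.08481,0.02516,0.04301,0.04167
Y,0.02869,0.08481,0.02516,0.04301,0.04167
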