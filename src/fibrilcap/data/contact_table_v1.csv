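# residue-pair contact potential v1 (dimensionless, lower = more favorable)
,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
A,-2.10,-2.22,-1.22,-1.22,-2.27,-1.73,-1.27,-2.55,-1.15,-2.43,-2.12,-1.22,-1.53,-1.22,-1.05,-1.67,-1.68,-2.50,-1.65,-1.58
C,-2.22,-2.33,-1.33,-1.33,-2.38,-1.85,-1.38,-2.67,-1.27,-2.55,-2.23,-1.33,-1.65,-1.33,-1.17,-1.78,-1.80,-2.62,-1.77,-1.70
D,-1.22,-1.33,0.27,0.27,-1.38,-0.85,-0.68,-1.67,-0.87,-1.55,-1.23,-0.33,-0.65,-0.33,-0.77,-0.78,-0.80,-1.62,-0.77,-0.70
E,-1.22,-1.33,0.27,0.27,-1.38,-0.85,-0.68,-1.67,-0.87,-1.55,-1.23,-0.33,-0.65,-0.33,-0.77,-0.78,-0.80,-1.62,-0.77,-0.70
F,-2.27,-2.38,-1.38,-1.38,-2.43,-1.90,-1.43,-2.72,-1.32,-2.60,-2.28,-1.38,-1.70,-1.38,-1.22,-1.83,-1.85,-2.67,-1.82,-1.75
G,-1.73,-1.85,-0.85,-0.85,-1.90,-1.37,-0.90,-2.18,-0.78,-2.07,-1.75,-0.85,-1.17,-0.85,-0.68,-1.30,-1.32,-2.13,-1.28,-1.22
H,-1.27,-1.38,-0.68,-0.68,-1.43,-0.90,-0.28,-1.72,-0.02,-1.60,-1.28,-0.38,-0.70,-0.38,0.08,-0.83,-0.85,-1.67,-0.82,-0.75
I,-2.55,-2.67,-1.67,-1.67,-2.72,-2.18,-1.72,-3.00,-1.60,-2.88,-2.57,-1.67,-1.98,-1.67,-1.50,-2.12,-2.13,-2.95,-2.10,-2.03
K,-1.15,-1.27,-0.87,-0.87,-1.32,-0.78,-0.02,-1.60,0.40,-1.48,-1.17,-0.27,-0.58,-0.27,0.50,-0.72,-0.73,-1.55,-0.70,-0.63
L,-2.43,-2.55,-1.55,-1.55,-2.60,-2.07,-1.60,-2.88,-1.48,-2.77,-2.45,-1.55,-1.87,-1.55,-1.38,-2.00,-2.02,-2.83,-1.98,-1.92
M,-2.12,-2.23,-1.23,-1.23,-2.28,-1.75,-1.28,-2.57,-1.17,-2.45,-2.13,-1.23,-1.55,-1.23,-1.07,-1.68,-1.70,-2.52,-1.67,-1.60
N,-1.22,-1.33,-0.33,-0.33,-1.38,-0.85,-0.38,-1.67,-0.27,-1.55,-1.23,-0.33,-0.65,-0.33,-0.17,-0.78,-0.80,-1.62,-0.77,-0.70
P,-1.53,-1.65,-0.65,-0.65,-1.70,-1.17,-0.70,-1.98,-0.58,-1.87,-1.55,-0.65,-0.97,-0.65,-0.48,-1.10,-1.12,-1.93,-1.08,-1.02
Q,-1.22,-1.33,-0.33,-0.33,-1.38,-0.85,-0.38,-1.67,-0.27,-1.55,-1.23,-0.33,-0.65,-0.33,-0.17,-0.78,-0.80,-1.62,-0.77,-0.70
R,-1.05,-1.17,-0.77,-0.77,-1.22,-0.68,0.08,-1.50,0.50,-1.38,-1.07,-0.17,-0.48,-0.17,0.60,-0.62,-0.63,-1.45,-0.60,-0.53
S,-1.67,-1.78,-0.78,-0.78,-1.83,-1.30,-0.83,-2.12,-0.72,-2.00,-1.68,-0.78,-1.10,-0.78,-0.62,-1.23,-1.25,-2.07,-1.22,-1.15
T,-1.68,-1.80,-0.80,-0.80,-1.85,-1.32,-0.85,-2.13,-0.73,-2.02,-1.70,-0.80,-1.12,-0.80,-0.63,-1.25,-1.27,-2.08,-1.23,-1.17
V,-2.50,-2.62,-1.62,-1.62,-2.67,-2.13,-1.67,-2.95,-1.55,-2.83,-2.52,-1.62,-1.93,-1.62,-1.45,-2.07,-2.08,-2.90,-2.05,-1.98
W,-1.65,-1.77,-0.77,-0.77,-1.82,-1.28,-0.82,-2.10,-0.70,-1.98,-1.67,-0.77,-1.08,-0.77,-0.60,-1.22,-1.23,-2.05,-1.20,-1.13
Y,-1.58,-1.70,-0.70,-0.70,-1.75,-1.22,-0.75,-2.03,-0.63,-1.92,-1.60,-0.70,-1.02,-0.70,-0.53,-1.15,-1.17,-1.98,-1.13,-1.07
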