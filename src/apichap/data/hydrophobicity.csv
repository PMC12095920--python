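# per-residue hydrophobicity, version 1
# Kyte-Doolittle hydropathy rescaled to [0, 1]; stand-in values, replaceable
# by any scale keyed the same way.
residue,hydrophobicity
A,0.700
R,0.000
N,0.111
D,0.111
C,0.778
Q,0.111
E,0.111
G,0.456
H,0.144
I,1.000
L,0.922
K,0.067
M,0.711
F,0.811
P,0.322
S,0.411
T,0.422
W,0.400
Y,0.356
V,0.967
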