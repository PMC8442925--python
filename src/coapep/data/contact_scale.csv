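# Expected number of residue-residue contacts within 8 A (packing-density
# scale) used as the default amyloidogenicity scale.  Hydrophobic residues
# exceed the empirical classification threshold of 21.4; polar and charged
# residues fall below it.  Values are a documented reconstruction of the
# published expected-contacts scale; see docs/methods.md.
residue,expected_contacts
A,19.0
C,21.6
D,16.5
E,16.0
F,23.7
G,17.5
H,20.0
I,23.5
K,15.4
L,22.8
M,22.3
N,17.0
P,15.5
Q,17.2
R,16.5
S,17.8
T,18.5
V,22.8
W,23.9
Y,22.3
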