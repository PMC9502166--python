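A	0.0826
C	0.0137
D	0.0546
E	0.0672
F	0.0386
G	0.0708
H	0.0227
I	0.0593
K	0.0581
L	0.0965
M	0.0241
N	0.0406
P	0.0475
Q	0.0393
R	0.0553
S	0.0660
T	0.0535
V	0.0687
W	0.0110
Y	0.0292
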