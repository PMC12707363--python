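# Mean (expected) packing density scale: average number of residue contacts
# within an 8 A sphere, by residue type (Galzitskaya, Garbuzynskiy & Lobanov
# 2006, PLoS Comput Biol 2:e177; used by the FoldAmyloid method with a
# hot-spot threshold of 21.4). Values transcribed from the publication line;
# the aliphatic/aromatic > threshold > charged/small ordering is the
# operative property for hot-spot calling.
# residue	contacts_8A
A	20.07
C	22.51
D	18.81
E	18.67
F	22.59
G	19.90
H	20.64
I	22.20
K	18.36
L	21.66
M	21.77
N	19.27
P	18.32
Q	19.32
R	18.92
S	19.75
T	20.48
V	22.06
W	21.74
Y	21.61
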