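# AGGRESCAN a3v aggregation-propensity scale (Conchillo-Sole et al. 2007,
# BMC Bioinformatics 8:65). Per-residue values derived from in vivo
# aggregation of A-beta mutants. Hot-spot threshold (HST): -0.02.
# residue	a3v
A	-0.036
C	0.604
D	-1.836
E	-1.412
F	1.754
G	-0.535
H	-1.033
I	1.822
K	-0.931
L	1.380
M	0.910
N	-0.784
P	-0.334
Q	-1.231
R	-1.240
S	-0.294
T	-0.159
V	1.594
W	1.037
Y	1.159
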