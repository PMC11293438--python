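# Default intrinsic solubility propensity scale ("composite-v1").
# Sign-inverted Kyte-Doolittle hydropathy plus a +1.0 charge bonus for D/E/K/R.
# Values are re-centred to zero mean at load time; only the ordering matters to
# the design pipeline. Substitute your own two-column file to use another scale.
# residue	propensity
A	-1.8
R	5.5
N	3.5
D	4.5
C	-2.5
Q	3.5
E	4.5
G	0.4
H	3.2
I	-4.5
L	-3.8
K	4.9
M	-1.9
F	-2.8
P	1.6
S	0.8
T	0.7
W	0.9
Y	1.3
V	-4.2
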