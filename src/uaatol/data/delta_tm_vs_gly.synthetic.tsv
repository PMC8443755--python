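# SYNTHETIC stand-in table: per-residue change in peptide melting temperature
# relative to glycine (degrees C). The published host-guest melting data this
# feature is defined on are not redistributed here; this stand-in is
# constructed from the helix-propensity differences of Pace & Scholtz 1998
# (Biophys J 75:422), negated and referenced to glycine so that residues that
# stabilise structure more than glycine score positive. Replace this file
# (keeping the two-column layout) with measured delta-Tm values to use the
# experimental scale.
# aa1	delta_tm_vs_gly_C
A	10.0
R	7.9
N	3.5
D	3.1
C	3.2
Q	6.1
E	6.0
G	0.0
H	3.9
I	5.9
L	7.9
K	7.4
M	7.6
F	4.6
P	-21.6
S	5.0
T	3.4
W	5.1
Y	4.7
V	3.9
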