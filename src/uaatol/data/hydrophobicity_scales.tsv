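# Side-chain transfer free energies (kcal/mol) for the 20 standard residues.
# kD_cyclohexane_water: cyclohexane -> water transfer free energy of side-chain
#   analogues (Radzicka & Wolfenden 1988, Biochemistry 27:1664).
# kD_vapor_to_water: vapor -> water hydration potential of side-chain analogues
#   (Wolfenden et al. 1981, Biochemistry 20:849).
# kD_octanol_to_water: octanol -> water transfer derived from the
#   Fauchere & Pliska (1983) pi scale (Eur J Med Chem 18:369), sign such that
#   hydrophobic residues are positive.
# Proline has no side-chain analogue in the cyclohexane and vapor scales; its
# entries there are set to 0.0 and flagged as undetermined in the source.
# This table is swappable: replace values and keep the header to use another
# scale set.
# aa1	kD_cyclohexane_water	kD_vapor_to_water	kD_octanol_to_water
A	1.81	1.94	0.31
R	-14.92	-19.92	-1.01
N	-6.64	-9.68	-0.60
D	-8.72	-10.95	-0.77
C	1.28	-1.24	1.54
Q	-5.54	-9.38	-0.22
E	-6.81	-10.20	-0.64
G	0.94	2.39	0.00
H	-4.66	-10.27	0.13
I	4.92	2.15	1.80
L	4.92	2.28	1.70
K	-5.55	-9.52	-0.99
M	2.35	-1.48	1.23
F	2.98	-0.76	1.79
P	0.00	0.00	0.72
S	-3.40	-5.06	-0.04
T	-2.57	-4.88	0.26
W	2.33	-5.88	2.25
Y	-0.14	-6.11	0.96
V	4.04	1.99	1.22
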