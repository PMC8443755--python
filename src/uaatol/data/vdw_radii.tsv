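# Van der Waals radii (Angstrom) used by the Shrake-Rupley surface
# computation (Bondi 1964, J Phys Chem 68:441, with S/P values as commonly
# used for proteins).
# element	radius
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
SE	1.90
F	1.47
CL	1.75
BR	1.85
I	1.98
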