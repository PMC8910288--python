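# Bound coherent neutron scattering lengths (fm), Sears compilation.
# symbol	b_coh_fm
H	-3.7390
D	6.6710
C	6.6460
N	9.3600
O	5.8030
P	5.1300
S	2.8470
Si	4.1491
Na	3.6300
Cl	9.5770
K	3.6700
Ca	4.7000
Mg	5.3750
Fe	9.4500
Zn	5.6800
Se	7.9700
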