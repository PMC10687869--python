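# Bound coherent neutron scattering lengths (fm), Sears compilation
# (Neutron News 3, 26 (1992)). D is the deuterium isotope of H.
# version 1
# isotope	b_fm
H	-3.7390
D	6.6710
C	6.6460
N	9.3600
O	5.8030
P	5.1300
S	2.8470
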