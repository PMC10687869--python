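# Displaced solvent volumes per atom (A^3), Fraser/MacRae/Suzuki convention
# as used by CRYSOL-family programs. United-atom group volumes are built
# additively from these (group = heavy + n_H * H).
# version 1
# element	volume_A3
H	5.15
C	16.44
N	2.49
O	9.13
P	5.73
S	19.86
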