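# LCPO (linear combination of pairwise overlaps) parameters: four-parameter
# fit per atom class. Classes are element + heavy-neighbor count, with an sp2 /
# carboxylate variant where the published fit distinguishes hybridization.
# radius = van der Waals radius (A); probe radius is added at evaluation time.
# version 1
# class	radius	p1	p2	p3	p4
C_sp3_1	1.70	0.77887	-0.28063	-0.0012968	0.00039328
C_sp3_2	1.70	0.56482	-0.19608	-0.0010219	0.0002658
C_sp3_3	1.70	0.23348	-0.072627	-0.00020079	0.00007967
C_sp3_4	1.70	0.00000	0.00000	0.00000	0.00000
C_sp2_2	1.70	0.51245	-0.15966	-0.00019781	0.00016392
C_sp2_3	1.70	0.070344	-0.019015	-0.000022009	0.000016875
N_sp3_1	1.65	0.73511	-0.22116	-0.00089148	0.0002523
N_sp3_2	1.65	0.41102	-0.12254	-0.000075448	0.00011804
N_sp3_3	1.65	0.062577	-0.017874	-0.00008312	0.000019849
O_sp3_1	1.60	0.77914	-0.25262	-0.0016056	0.00035071
O_sp3_2	1.60	0.49392	-0.16038	-0.00015512	0.00016453
O_sp2_1	1.60	0.68563	-0.18680	-0.0013557	0.00023743
O_carboxylate_1	1.60	0.88857	-0.33421	-0.0018683	0.00049372
S_sp3_1	1.90	0.78602	-0.26393	-0.0010629	0.00029542
S_sp3_2	1.90	0.54581	-0.19477	-0.0012873	0.00029247
P_sp3_3	1.90	0.38650	-0.18249	-0.0036598	0.0004264
P_sp3_4	1.90	0.03873	-0.0089339	0.0000083582	0.0000030381
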