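# Published conformational entropies ln(omega_{H2,l1,l3}) for the
# hairpin-hairpin kissing complex, in units of k_B, indexed by kissing-stem
# length h2_len (bp) and bridging-loop lengths l1_len/l3_len (nt).
# Empty ln_omega = cell printed as '-' (infeasible/not tabulated); rows not
# printed in the source (l1=1 for H2 in {3,4,7,8}) are also stored as
# missing.
# unverified cells (ambiguous digit grouping in the source text, excluded
# from tests): (3,3,3), (4,4,4)
# provenance: published table (transcribed); coil reference ln(omega_coil)=2.05*l+0.1
h2_len	l1_len	l3_len	ln_omega
3	1	1	
3	1	2	
3	1	3	
3	1	4	
3	1	5	
3	1	6	
3	1	7	
3	2	1	
3	2	2	0
3	2	3	0
3	2	4	1.8
3	2	5	2.6
3	2	6	4.2
3	2	7	5.8
3	3	1	
3	3	2	0
3	3	3	
3	3	4	1.6
3	3	5	1.1
3	3	6	1.4
3	3	7	2.5
3	4	1	
3	4	2	1.8
3	4	3	1.6
3	4	4	3.8
3	4	5	4.2
3	4	6	5.8
3	4	7	7.4
3	5	1	
3	5	2	2.6
3	5	3	1.1
3	5	4	4.2
3	5	5	4.1
3	5	6	5.4
3	5	7	7.0
3	6	1	
3	6	2	4.2
3	6	3	1.4
3	6	4	5.8
3	6	5	5.4
3	6	6	6.3
3	6	7	7.8
3	7	1	
3	7	2	5.8
3	7	3	2.5
3	7	4	7.4
3	7	5	7.0
3	7	6	7.8
3	7	7	9.3
4	1	1	
4	1	2	
4	1	3	
4	1	4	
4	1	5	
4	1	6	
4	1	7	
4	2	1	
4	2	2	1.1
4	2	3	0.7
4	2	4	1.4
4	2	5	3.4
4	2	6	5.0
4	2	7	6.7
4	3	1	
4	3	2	0.7
4	3	3	1.4
4	3	4	0.7
4	3	5	3.4
4	3	6	4.9
4	3	7	6.6
4	4	1	
4	4	2	1.4
4	4	3	0.7
4	4	4	
4	4	5	2.7
4	4	6	4.1
4	4	7	5.7
4	5	1	
4	5	2	3.4
4	5	3	3.4
4	5	4	2.7
4	5	5	5.3
4	5	6	6.7
4	5	7	8.4
4	6	1	
4	6	2	5.0
4	6	3	4.9
4	6	4	4.1
4	6	5	6.7
4	6	6	7.9
4	6	7	9.5
4	7	1	
4	7	2	6.7
4	7	3	6.6
4	7	4	5.7
4	7	5	8.4
4	7	6	9.5
4	7	7	11.2
5	1	1	0
5	1	2	1.4
5	1	3	1.4
5	1	4	2.8
5	1	5	3.7
5	1	6	5.2
5	1	7	6.7
5	2	1	1.4
5	2	2	2.8
5	2	3	2.4
5	2	4	4.1
5	2	5	4.8
5	2	6	6.3
5	2	7	7.8
5	3	1	1.4
5	3	2	2.4
5	3	3	2.1
5	3	4	3.7
5	3	5	4.4
5	3	6	5.8
5	3	7	7.3
5	4	1	2.8
5	4	2	4.1
5	4	3	3.7
5	4	4	5.4
5	4	5	6.1
5	4	6	7.6
5	4	7	9.0
5	5	1	3.7
5	5	2	4.8
5	5	3	4.4
5	5	4	6.1
5	5	5	6.8
5	5	6	8.3
5	5	7	9.7
5	6	1	5.2
5	6	2	6.3
5	6	3	5.8
5	6	4	7.6
5	6	5	8.3
5	6	6	9.7
5	6	7	11.2
5	7	1	6.7
5	7	2	7.8
5	7	3	7.3
5	7	4	9.0
5	7	5	9.7
5	7	6	11.2
5	7	7	12.6
6	1	1	
6	1	2	
6	1	3	
6	1	4	
6	1	5	
6	1	6	
6	1	7	
6	2	1	
6	2	2	0
6	2	3	0.7
6	2	4	1.1
6	2	5	2.2
6	2	6	3.3
6	2	7	4.7
6	3	1	
6	3	2	0.7
6	3	3	1.8
6	3	4	2.3
6	3	5	3.7
6	3	6	5.1
6	3	7	6.7
6	4	1	
6	4	2	1.1
6	4	3	2.3
6	4	4	2.7
6	4	5	4.0
6	4	6	5.2
6	4	7	6.8
6	5	1	
6	5	2	2.2
6	5	3	3.7
6	5	4	4.0
6	5	5	5.5
6	5	6	6.6
6	5	7	8.2
6	6	1	
6	6	2	3.3
6	6	3	5.1
6	6	4	5.2
6	6	5	6.6
6	6	6	7.6
6	6	7	9.2
6	7	1	
6	7	2	4.7
6	7	3	6.7
6	7	4	6.8
6	7	5	8.2
6	7	6	9.2
6	7	7	10.9
7	1	1	
7	1	2	
7	1	3	
7	1	4	
7	1	5	
7	1	6	
7	1	7	
7	2	1	
7	2	2	
7	2	3	
7	2	4	
7	2	5	
7	2	6	
7	2	7	
7	3	1	
7	3	2	
7	3	3	
7	3	4	
7	3	5	
7	3	6	
7	3	7	
7	4	1	
7	4	2	
7	4	3	
7	4	4	2.2
7	4	5	3.3
7	4	6	5.0
7	4	7	6.7
7	5	1	
7	5	2	
7	5	3	
7	5	4	3.3
7	5	5	4.2
7	5	6	6.0
7	5	7	7.6
7	6	1	
7	6	2	
7	6	3	
7	6	4	5.0
7	6	5	6.0
7	6	6	7.8
7	6	7	9.5
7	7	1	
7	7	2	
7	7	3	
7	7	4	6.7
7	7	5	7.6
7	7	6	9.5
7	7	7	11.2
8	1	1	
8	1	2	
8	1	3	
8	1	4	
8	1	5	
8	1	6	
8	1	7	
8	2	1	
8	2	2	
8	2	3	
8	2	4	
8	2	5	
8	2	6	
8	2	7	
8	3	1	
8	3	2	
8	3	3	
8	3	4	0
8	3	5	2.2
8	3	6	4.1
8	3	7	6.1
8	4	1	
8	4	2	
8	4	3	0
8	4	4	0.7
8	4	5	2.4
8	4	6	4.2
8	4	7	6.1
8	5	1	
8	5	2	
8	5	3	2.2
8	5	4	2.4
8	5	5	3.9
8	5	6	5.5
8	5	7	7.3
8	6	1	
8	6	2	
8	6	3	4.1
8	6	4	4.2
8	6	5	5.5
8	6	6	7.0
8	6	7	8.7
8	7	1	
8	7	2	
8	7	3	6.1
8	7	4	6.1
8	7	5	7.3
8	7	6	8.7
8	7	7	10.4
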