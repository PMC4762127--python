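# Minimal nearest-neighbor stack parameters for RNA duplexes.
# stack "XY/WZ": top strand 5'-XY-3' stacked on bottom strand 3'-WZ-5'
# (X pairs W, Y pairs Z).  dH in kcal/mol, dG37 in kcal/mol at 310.15 K.
# Watson-Crick values are the standard experimentally fitted RNA set; the
# wobble (G-U) subset is a minimal complement sufficient for toy systems.
# Special terms: "init" (duplex initiation) and "terminal_au" (per AU or
# GU terminal pair).
stack	dH	dG37
AA/UU	-6.82	-0.93
AU/UA	-9.38	-1.10
UA/AU	-7.69	-1.33
CU/GA	-10.48	-2.08
CA/GU	-10.44	-2.11
GU/CA	-11.40	-2.24
GA/CU	-12.44	-2.35
CG/GC	-10.64	-2.36
GG/CC	-13.39	-3.26
GC/CG	-14.88	-3.42
AG/UU	-3.21	-0.55
AU/UG	-8.81	-1.36
CG/GU	-5.61	-1.41
CU/GG	-12.11	-2.11
GG/CU	-8.33	-1.53
GU/CG	-12.59	-2.51
GG/UC	-12.83	-1.27
GU/UG	-13.47	-0.50
UG/AU	-6.99	-1.36
UG/GU	-9.26	0.30
GA/UU	-8.00	-1.30
GG/UU	-10.60	0.47
init	3.61	4.09
terminal_au	3.72	0.45
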