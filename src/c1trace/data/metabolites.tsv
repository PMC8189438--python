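# Default metabolite panel for tryptophan/serine/formate tracing.
# slots: pool:count pairs joined by "+"; carbons not covered by a slot are
# unlabeled under every tracer. Pools: trp_intact (intracellular tryptophan,
# transferred wholesale), one_carbon (10-formyl-THF), methyl (5-CH3-THF),
# glycine (per-position).
# name	formula	n_carbons	slots
tryptophan	C11H12N2O2	11	trp_intact:11
kynurenine	C10H12N2O3	10	trp_intact:10
formate	CH2O2	1	one_carbon:1
serine	C3H7NO3	3	one_carbon:1+glycine:2
glycine	C2H5NO2	2	glycine:2
methionine	C5H11NO2S	5	methyl:1
AMP	C10H14N5O7P	10	one_carbon:2+glycine:2
ADP	C10H15N5O10P2	10	one_carbon:2+glycine:2
ATP	C10H16N5O13P3	10	one_carbon:2+glycine:2
GMP	C10H14N5O8P	10	one_carbon:2+glycine:2
GDP	C10H15N5O11P2	10	one_carbon:2+glycine:2
GTP	C10H16N5O14P3	10	one_carbon:2+glycine:2
acetyl-CoA	C23H38N7O17P3S	23	one_carbon:2
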