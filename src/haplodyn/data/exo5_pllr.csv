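haplotype,protein_change,pllr
haplotype1,WT,0.0
haplotype2,G172V,5.05
haplotype3,G172V+D115N,4.51
haplotype4,L151P,-2.74
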