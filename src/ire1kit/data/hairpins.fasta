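>BIP1 S. pombe BIP1 mRNA 3'UTR cleavage-site hairpin (RIDD-like stabilizing cut)
CGCGAGAUAACUGGUGCUUUGUUAUCUCGCG
>SPAC4G9.15 S. pombe SPAC4G9.15 mRNA RIDD cleavage-site hairpin
CCACCACCGAGUAUGCUACUCGGUGGUGG
>HAC1_3SS S. cerevisiae HAC1 mRNA 3' splice-site hairpin
GCGCGGACUGUCCGAAGCGCAGUCCGCGC
>XBP1 human XBP1 mRNA 3' splice-site hairpin (dual-specificity substrate)
UGCACCUCUGCAGCAGGUGCA
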