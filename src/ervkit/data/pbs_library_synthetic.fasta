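>Arg
AGGAAATTCATGCTATAC
>Lys
GTTTCTGATGTTTGGGTC
>Trp
TCGCGTTGTGAGCCGAAA
>His
CTAGCGATGTAAAACCCC
>Ser
TCTCGGCATCATTCACGT
>Leu
CCGAGCCGATGTCAGCTG
>Gly
ACAGAGTTTGGGACAAGA
>Pro
TCTTGGCCGAATTGCACC
>Thr
GACCCTTCGTGTAGACGC
>Val
AGGCCCTTAGACACACAA
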