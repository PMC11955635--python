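>TRBV-T1
GTCCATGCCACATGTGGTATATTACGTAAGCACCCAGTTGTACCCTTGGAACCTGTCCAATCGATATCAGACGCCTATAACGTTCTGGTAGCAATGGGAGCCGGCTGTGCCAGCAGCACG
>TRBV-T2
AACTACCTCTCGAAAACGTTCAATTTGTTAAATCTGTTTAGGACTGTATACGTCGTCTGTCGACTGGAAGAACCCGAATCCATGTGCCGTTCGCATCGGGTGATGTGTGCCAGCTCCACT
>TRBV-T3
GGGAGTATCCGCGTTTCTAGACCAGAGCCGGGGCAAATTGAGTCATATTTCTACCTGAAAACTTCTCGAACGTGGAACTATACCCCGTTGGTTGGGGATCCTCTATGTGCCTGGAGCCGG
>TRBV-T4
TATTTAAATAACCTGCAGGGGTTCCGACCTCGATTGGCCCTCGGGAGTGCAAGGTGCCGTAGAAACCTTATGTCGTGTCGAAAAGGGTCCAATGGCCGTAATGCATGTGCCAGCAGTGCA
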