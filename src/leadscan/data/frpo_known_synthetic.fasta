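>frpo_standin_00 synthetic stand-in ssDNA promoter (UP/-35/-10/stem architecture)
AAACCCTAATTTATAATTATTTATAATTTGACAATCGATATCCGCCTTGTTATAATGTTCATTATAACAA
GGCGGATATCGATTGTCAAGAACAGTTCGACC
>frpo_standin_01 synthetic stand-in ssDNA promoter (UP/-35/-10/stem architecture)
AGCGCTGACGGGTAATTAAGAATTAAAAACTTTTGACAACGTCAGGGTGATGAGATATAATACTAATTAT
ATCTCATCACCCTGACGTTGTCAACGAAGTGGGA
>frpo_standin_02 synthetic stand-in ssDNA promoter (UP/-35/-10/stem architecture)
ATGGCCTTATTATTTTTAATATTATATTGACAACTTTAAGGTTAGATTCTATAATGGCCATTATAGAATC
TAACCTTAAAGTTGTCAAACACGGCTTT
>frpo_standin_03 synthetic stand-in ssDNA promoter (UP/-35/-10/stem architecture)
CGAGCATGATTTAGTATTAATCTTTTTGACAAGCATAGACATTGAGCTTATAATTGCTATTATAAGCTCA
ATGTCTATGCTTGTCAAGTCTGAGTG
>frpo_standin_04 synthetic stand-in ssDNA promoter (UP/-35/-10/stem architecture)
AAACATCTTTGATTTAATTAATTTGTTATTATTGACATCCTCCTATGAATCGTATATAATTCTAATTATA
TACGATTCATAGGAGGATGTCAATTCATGC
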