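>oriT_standin_00 synthetic stand-in oriT query (not a database sequence)
TCATGTAAAGATAACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATGGAATAACCCCAGCCC
AGGGCAAGGCAGCACTCCGTAAGCGACGGAGCAGTCCACCCATTTATTGGCACGCGGTCTCCCTTCCGAT
GACACCA
>oriT_standin_01 synthetic stand-in oriT query (not a database sequence)
CGGCTCCGCCCATCGGGTTTATTGGGTTTTGTGGAAGCTGTCGATCACCAGCCTAGGCAAGGGTAAGGGT
GCTAAATGCAGGACTGCGAGGAACAAACGTTCTCTGCGACTAGGAGGTTGACCGTGGCGAGA
>oriT_standin_02 synthetic stand-in oriT query (not a database sequence)
CCCGTGAAGATAAACCTAGAAGATTGGATCATCAGAGTGAACATGACCAGGCCCTATCGAGTTGTTATGG
GTTCTAGATTTACAGCGCTGGATGACTATGCGACTCTCCCGATTCTGGTTATCAAGGTATCGCGTTATTC
GCATGCTTTCGCCAGATGAAGGTATTTAATTCGCTAAATGTAGTACTGTCGAGAGAGAGAAAACCATGGG
TGGTTACCCCTGCAAGTGGAAAAACTGACACCC
>oriT_standin_03 synthetic stand-in oriT query (not a database sequence)
CTTGGCAAGTTTGTGTAGACGCCAGATGGTACCTGTATATCCTGTGCCCCCGGGACAGGCCAGGATTTAA
TTGATTTAAGCTGGAGGAAACCTTTACGCAGTTGTAGACGATCCAGATCTTGTCACAGACTATTTTAGTA
GAGAAGTA
>oriT_standin_04 synthetic stand-in oriT query (not a database sequence)
CTGGTCGAGGACAGGATTGGGTAGCGTTGGAAAAGAGCGGTATGTCTGTCCTTTACGGGGTGGGACCTCC
ACGGACACTCCTTTTTGTACCTTAGGACAACGCATTTTTATACAATCCGCATACTTATCCAT
>oriT_standin_05 synthetic stand-in oriT query (not a database sequence)
ATGGGTCATAACGTCACGCGTTCGGGTCATCAATCCAGTCATTGGCCATAATTCGCTGAGTCCCATTAAG
GGGGAAGAACTTTCCACTTTCAGTTCGGCACATGGCACGCCCCTTGAGGAATCCTTACTTGACTCAACTT
GCGGCTTAGAGCGTAAGCGTCGATGGTAGCGAGTCTTAGCATTTGATATTTGCGCTAGGCGG
>oriT_standin_06 synthetic stand-in oriT query (not a database sequence)
ACTTAACCGCCCCGCATTGTCTTTAGTTTACGTTATTTATCAACGCGTCCTGATCCTACGAGACTCCCGA
ATTCCCCCTGATCCCGGTTTCACTAAGTTAAAGGCTGCAACGACTAGGAGACAATCAAGGGTTCCAAGTC
TTCCTTGTCCAATGGCAGGGAATAATCGTATCGTGTACAACCCAGAG
>oriT_standin_07 synthetic stand-in oriT query (not a database sequence)
CTGAAAGCAGTGCCATCTTGGCAATTAGCGAATGTGTTTGGGCAGTCACAGCAATGCCTACCGTCGCTTA
CGTTATTGGTATTCCACCGACAGTGCGCCTGTCAAGCGCATGCACCCATAATGGAGTATACCTTACCGGT
TACTAACTGCCAAATGTTTCCCTAAAGCGGCGTTT
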