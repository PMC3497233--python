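>t0
ACGAATAATGCGGCATGGTGTAGCCGATTACCATCAGATAAACCTGCAATCGAATGCCAAATCAGAAGTATAAACGCTACCTTCCCGAACATGGGGTTAGACTTTACATAACATGACAGAAAGGCGCACCTAAGTTGATGACATGTTCTAACCCGGAGCGCTCGGGCTACGAATTGTTCGCGCATGGGGCGAGTGTCTATCAGCCTAGCGCAGTAAACTATGACAGGCCTTCCGTAACGAAACGGAACTTCTTCGCAGAGTTCATTTGGCACGCGGCTACATCCAGCAACGGTTTTCGCC
>t1
GCGAATTATGAGCCCCGGTGTAGCGGCTTACCATCTGATCAACTTACCTTGCAGTACCATGTCAGAAGTACCATCGCGACATTCTCGAACATGGGAGCGAACTGTACACAACTTTAAAGAGAACCGGACCGAGGCTGATTAGATGTGTTAACCTGGACCGCGTGGGCTGAGTATGGTTGGCACAAAGCTTGGGTGTCAATCTGCAGATCCCAGTAAACTAAGACTGTCATACGAAAACTCTGCCGAACCGCGTCGCGCTGTTCCCCTAGCCGGGGGCTTAGTACAACAACCGTTTTCGGA
>t2
ACGAATAATGCAGCATGGTGTAGCCGATTACCATCGGTTCGACCTACAATCGAATGCCAAATCAGAAGTATCAACGCTACCTTCCGGAACAAGGGATTAGACGTTACATAACTTGACAGAAAGGCGGACCTAAGTTGAAGACATGTTCTAACCCGGAGCGCTCGGGATAAGCATGGTTCACACAAGGGTCGAGTGTCTATCAGCCTAGCGCAGTCACCTATGACAGGCCTTCCGTAACGAAGCGGAACCTCGTCGTAGTGTTCATCCGGCACGCGGCTGCATACAACAACGGTTTTCGCC
>t3
ACGAATAATGCGGCATGGTGTAGCCGATTACCATCGGATACACCTACAATCGAATGCCAAATCAGAAGTATCAACGCTACCTTCCCGAACATGGGGTTAGACTTTACATAACATGACAGAAAGGCGCACCTAAGTTGATGACATGTTCTAACCCGGAGCGCTCGGGCCACCAATTGTTCGCGCATGGGTCGAGTGTCTATCAGCCTAGCGCAGTAAACTGTGACAGGCCTTCCGTAACGAAGCGGAACCTCTTCGCAGAGTTCATTTGGCACGCGGCTTCATCCAACAACGGTTTTCGCC
>t4
ACGAATAATGCGGCATGGTGTAGCCGATTACCATCAGATAAACCAGCGATCGAATGCCAAATCAGAAGTATCGACGCTACCTTCCCGAACATGGGGTTAGACTTTCGATAACATGACAGTACTGCGCACCTACGTTGATGACATGTTCTAACCCGGAGCGCTCGGGCTACGACTTGTTCGCGCAAGGGTCGAGTGGCTACCATCCTAGCGCAGTAAACTAAGACAGGCCTTCCATAACGAAACGGAACTTCTTCGCAGAATTCACTTGGCACGCTGCTCCATCCAACAACGGTTTTCGCC
>t5
GCGAATTAGGAGCCCCGGCGTAGCGGCTTTCCATCTGTTCAACTTACGTTGCTGTACCGTGTCAGAAGTGACATCGTGACATTCACGAACATGGGAAAGAACTGGACACAACTTTAAAGAGAACGGGAGCGGGGCTGATCTGATGTTCTGGCCTGGACCGCGTGTGCTGAGTGTGGTTGTCACAAAGCTTGAGTTCCTATCTGCAGAGCCCAGTAAACTAAGACTATCATACGAAGACTCTGCGGAATCGCGTCGCGGTGTTGCTCTAGCCGGGGGGGTAGTACAAGAACCGTTTTCGGA
>t6
GCGAATTAGGCGGCCCCGTGGAACGGATTTCTATCTGATCCACTTACCTTGCAGCACGAAGTCCGAAGAAGCATCGCGACATTCCCGAACATAGGACAGAACTCTAAACAACTTTAAAGAGAACGGGACCGTGCCTGATCAGATGTTCTCACCTGGACCGCGTTTCCTGGGTATGGTTGGCACAAAGCTTGGGTGTCTATCCGCAGAGCCCAGAAAACAAGGTCTGTCATACGAAAACACTATGGAACCGCGTCGGGGTGTTGCTCTAGCCAGGGGGATAGTACAACAATCGATTTCACA
>t7
ACGAAAAATGCGGAATGGTGTAGCCGATTACCTTCAGATAAACCTGCAATCGAATGCCACATCAGATGTATTAACGCTACCTTCCCGACCATGGGGTCAGACTTAACATAACATGACAGAAATGCGCACGTAAGTTGATGTCCTGTTCTAACCCGGAGTGCTCGGGCTACGAATTGTTCGCGCCTGGGTCGAGTGTCTATCAGCGTAGCGCAGTAAACTATGGCAGGCCTTCCGAAACGGAACGGAACTTCATCGGAGAGTTCGTTTGGCACGCGGCTACATCCAGCAATGGTTTTCGCC
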