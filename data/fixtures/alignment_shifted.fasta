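>t0
CTAACAGATTAGACCCCTCAGTTTATGTCATGTAATATAGCCATTGGGGGTCATTCTGTATGCGGCCTTACTTTATGAAAAGCGATGTGCATAGAAGTCTTGTCAAAATTAGTGCCGATAATAAAAATGCATCTGAATAACCCTCTACTCTCCTCGGAAAAGGCCACTAGGACAGCACATGCCGTCAAAAGCTTATGTATCACTCCTTTATGTTTTGAGACCCTTTGTACTCCTATGACTCAAGAAATTAGGATGGCTTCATCCTGGTTGTTTTATTAGGCCGACGGGTTTGAAGGAATT
>t1
TTAGCTGACGCGACACCGATGTGCATGACATGTACTCGCGCCATTTGGCACCAGTCGTAGGGAAGGCGAGTGTTATGAAACGCGTGGTGCATTCGAGTGGTGTCAAAAATAGTGCGGGTAGTAAAACTGCCACTCAACTTCACTCTTGTCTCAGCGGAACAGGCAATTAGGTCAGCATTGGGCGTCAAGAGCCTGTTGATGCCTCCTTTAGGGCTAGTAACCCTCTTTTCTCCGCGATCTCTAAAAATTAGGATCGCCAAATCTTGGTAGTTTTTTTAAGCCGCCGCTTTTGAACTAATT
>t2
CTAGCTGACGAGACCCCTACGTTTATGTCATGTAATAGAGCCATTGGGGTCCATTTGGTATGCGGTCGTGCGTTATGAAAAGGGTTGTGCATACAAGTCGTGTCAAATTTCATGCCGTTAGTAAAAATGCCACTCAATTACGCTCTACTCTCATCGGAAAAGCCCACTAGGACAGCATAGGCCGTCTAAAGCTTATTGAGCACTCCTCTATGGTTTGAAAACCTCTGTTCTCCTATGACTCAACAGGTTAGGATGGCTCCATTCTGGCTGTTTTTTTAAGCCGACGGGTTTGAAGGAATT
>t3
CTAACTGATCAGATCCCTCAGTTTATCTCATGTAATAGAGCCATTGCTGGCCATTCTGTATGCGGCCTTACTCTATGAAAAGCGTTGAGCATAGAAGTCTTGTCAAAATTAGTGCCGATAATAAAATTGCATCTCAACAACCCTCTACTCTCATCGGAAAAGGCCACTAGGACACCATATGCCGTCAAAAGCTCGTGTATCACTCCTTTATGTTTTGAAACCCTTTGTGCGCCTATGACTCAACAAATTAGGATGGCTTTAGCCTGGTTGTTTTTTTAGGCCGACGGGTTTGAAGGAATT
>t4
CTAACAAAATAGACTCATAGGTATATAAAAAGTGGGATCGACCAAGGGGGTGAATAAGTATGCGGCCTTGATATAAGAAAAGCGATGTACATAAAAGTCTTGTAAAAATAAATGCCGAGAAACAAAATGCATCTAAATAACCCTCTACTATCATCGGAAAAGGCCACTAGGACAGCACATAACTTAAAAAGCAGATGTAAAACTCCTTTATACAATGAGAAACTTTGTACTCCTATGAATCAAAAACTTAGGATAGCCTCATATTAATAATTTTATTAGGACAACAGGTAAGAAGGAATT
>t5
TGACCTGAAGCGACACAGAAGTACATGACCTGTACACGCACCATTTGACAGCAGTCATAGAAAAGGTGAATGATCAGAAAAGCGAGGTGCATTCGAATGGAGCCTGACATAGTGCAGGTACTAAAAATGCCACTCAACTTCATTATAGCCTCAGCGCATCAAGACACTAGGACAGCATAGGTAGTCAAGTACCTGTGGATGGATCCTTAATGACAAGTAAACCTCATATATCAAGGAAATCTAAAAATAAGGATCGTAAAATCTAGATAATATTTTTAGACCAACGCATTAGAAAGAACT
>t6
TTAGAGTGGGCGAAACCGATGTGCATAACATGTAATGGAGCGAGTTGGCACAAAACGAAGAGAAGGTGACTATTATGAAACGCCTAATGCAATCGTGAGGGGTCAGGCTTAGTGTGGGTAATAAAACGGATAAATAAATATACTCATGAATCAAAGCATCAGAAAATTAAGACAGAAGGAAGCGACAAAACGATGAAGAATCATCCCTTATGGCAAATAAAGATATATTATCCGAAGCCAAAAAAAATTAAAATCGCCAAAACAATATCCTAATTTTAAGACGCCACTTTAGAAAGAACA
>t7
CTATCAGAAAAAAAACATGATTTAATGAAATGTAATAAAGCAAGTGAGGAAGCGTCAATAAGCGGACTTACTATATGAAAAACAATGTACATAAAAATACTGTAAAAATAAGTACCGAAAATAAAAATGCATCAGAATAAACCTAAACTCTACTAAGAAAAGGCCACTAGGAAAGCACATTCCATAAAACGCCTATGTATCAATACTTTAAAATCATAGAACCTTAGAAATACAAAAACTTAAGCCATTAGGGAGGATTCTACCAGGATGATTAAATAGGCCGACGGGATTAAAGAAGTA
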