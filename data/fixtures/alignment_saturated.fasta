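>t0
TTTCATGATTCTACTCGATCATTAGTAGTAAGGGGAGCATGCGCGGGGGTATCCGGAGCACCTATTGATACGCCCACTTAGCCTTGGTCTGGCGTCTCGCCTCATCGAGGCGTGTCCCCTCAGCGATCGGCTAGCAATTTCCACCACTGCATAAATTAGGGAGCTTGACGTCCGTAGGCCTTAACCACTGTTCGGGGTGTCACTCGCTATAGGACCCACACGCCGGAACTGGAGCAAAGGTCGGGTAGAGCCTAATCCAGGTCATCGTTACCTCCTAAAGACCGCATTGCTATGCGGACT
>t1
GAGCCACCGACATACAGTGGTACCTGTGCGAGGAGATAGCCCAAATTACGGTCATAACACCACATGGTTAATCTATATCGAAGCACTAATAGCGTCAGCGGACATCGAAAAGTTCAGCGTATTCCGCCGTCTGGGACGCTCGGCGGTTACAAAATAGCGAGCGCAATGTCCTGTAAATGCGTCAGATAGGGGTCGAGGTAATGGTCAGAGATGCGATTGAGGACAGGGGTGTAAAGTCTGCCCAAAAGCACAGCCCTCGATAAGTCATGCTGGAGCACGTTCTCGGACGAGTTAGCTTTA
>t2
TTACGTGCTTGGACTCGTTAGCTAGACGAATCCAACGCGCGCGCAGGTGCTACCTAGGCACGTATGGATTCTCGCACTTCGAGACTTCATGGAGGATGTACTCGTCCTTGACTTGGCTGGCTGCACTCAGGTGTCTGATGCGACAACTCCAAAAAAATGGGCTCGATCCGGTCGTCGCCGTCGAACTAGTGCCTGGGTTCTTTTGGGCATAGAGCGGCCAAGTCTCATAGACAGCACCGTTCGGGCCGCTCGACAGCCTGGACCTCAGTATCTATCAAAAACTGCTCTGGCTTGGGGCAC
>t3
TTACATGCTTTTACAGGTTAAATGGTGGTAAGGAGAGCCTTCGCACGGGTTTCAGGCGCACCTATTGATGCGGCCACTCTACCTTGGCTTGTCGTCTCGGCTCATCGTGGAGTGACCCATCAGCGCTCGGCTGGTAAATTCAACAACTGCCTAAAACTGCGAGCTTGACGTTCCATAGCCTACACCACGGGGCGGGGTTTGAGTGGGTATAGCTCCCACACGCCGAAAATGGAGCAACGTTCGGGTATCGTCCAAACCCAGTGTTTATTTCCGGCCAAAAACCGCTCTGCTATGCTGACC
>t4
AGTAGAGCTCATATGTGGTCATCGGTCATCCGGGCCGCATGCGCAGGATGATGCGGGTCACGTAGTTGGAGTACGACTTAGACTTGTAAAACCTTCTCTCCACAGCGTGGCCAATCGCAACAGCCCTTTGCGAATAATTTGCGCCACTGACCACATCGGGGTGACTTCCGTGCGTAGGCTCACGACATAGGTCGGGGTTCAAATCGTTATAGAACTCACACGTGGAAACCAGAGCATAGGTTGGCGCGAGCATCCGCACGACCATTGTTACCGTCTCAAGCTCGTAACCCTTTGCGGTCC
>t5
GAATCGCAGCCACTCTATGATACGGGATCCACCGGATAGTACAAGTAGAGATGATGGAAAACCGCAGTGAGCCGTCAGCCGTAGATTCATTAGGTCACCGAACCCTTGCAAGTGCGACTTACCACCCAGTGACATTTGCTGGTCGGATCCGACTGAGGCTTGGCGACGAAGCCTACACGCGTCATCTGGTATTCCTCATCATGCATAGTGATGCGTTTGACTACATCCTTGAAACGACTGGGCCTAACAAGAGGTGGCTATGACAATTCCGCCAGAATACCCTCCCCCGAGAGAACGCTA
>t6
TAGGCGCCGTATCACTACCTTCACGAATCGGGCTGGTGGTACGACGCGCTATCCAGAGAGCGCCACTTCTTTCTAGAATCAAGCAGATAGATTCACAGAGAGTAAGGAAAGAATATATTTGCTTGCGGGCAATATTTGGTGAGCGACCCGAGATAAGTAGGCGCAGATCGATTTAAATCCCGAATTAAGTTATCGAAGGCCTGTATAGTGATTTCAACCCTGTTTTCACTGGAAGGCCTTACCGGATTAGCAAGCCCATCTCTCTTCCTCTTACGACGATGCGCGTACAGAGTGGCGGCG
>t7
ATTCCATGACCGAGTGGACCATTGAGGGTGACGGAGGGGTGCGCCGCGAAGTCTGGCGCGCCTATTAATTCGAACATGGAGTCATGGTCTAGCATCTCCGATCATCGGGACATAGCAGCCCAGCGGGCGGACGACAATTTCCTTCACTACGTAAATCATGGGGCCTGATGTCCCTAGGACTACTCTACCTTTCTGGGTTCCACTTACGAATGGACCAACCCGACGGAGCTGGAGACTAAGCAAGTCAGTTCAATTGCCAGCAGGCCAGGACCTCCTAAACACCGTATTTCGATGGCGACT
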