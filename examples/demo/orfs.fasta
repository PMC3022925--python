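>G0001 synthetic ORF
ATGTGGTTGGATACGAAACAGATTCATAGAGGGAGCGGATCTGCCGAGATTCTATCGGGC
ATTTGGTCACACGGGTCGGCTGCCGTCAAACTGGTCTCAAAGATCGCTAGTGCGTTAGTG
TTATGTTATATGGCACGTCGGCTCATTTGGGGATTGCCAGCTAAGAGGCCAAGAGGCCCC
TGTGACCTGCGAATAGGCAATGTCACCATTAATGTAACGACTCAATTCCGTTAG
>G0002 synthetic ORF
ATGCAATCATCTTCACATTTGCGGTATGGGCCACGTCGTAGTATAGTGACACGATTGCGG
TCTAGCACCCCTGCGGGACCCAGGAACGAGAATGCGGCAGGACGCTATGCCGACAGCACC
GTAAATGTTCTCTACATCGAGTGCTCGCAGAATGGTTTTGGCTTGCTGATGGTTGAAGGA
GCTTTTAGCGTATACGTAGTGTGGGTCCGTGTCGAGCCAAGCCTATTGCTATTAAAGCCC
GGTCCGTTTAGAGTATGA
>G0003 synthetic ORF
ATGTCATTACCGATGCCCAGACAGTCCCAACGATGTAAATTACCCCCTACAACAAGCCTG
GCCGAAGAAGGTGCTCCGAAGCCCGTGCTCCGGCTTCAACGTCCCGCCTATGGTAATATA
AGTACTATTTGTGAGGCTGGGTCAGGTGAATCTCAAAGTTCTGCTTCAAAAGCGCTTCAC
GTATCAAATGAGCTTAAGTCCTTGACTTATCATCCATTCCTTCTAATGTGGGAACTCCAG
TATCTATGCATATGTGTTGTGCACTGGAGATCGGACGCTTAA
>G0004 synthetic ORF
ATGCCTAGGACCCTTGACGGGCTAATTGCACAACTCTTACTACTGCGCCGGTGTTTTTTT
TATGATCTCATATACGTTTCTGGAGGGTATATCGTAATACAGGGGGCTGTTCGTGCGATG
TTAAGGGCAGTAGGTAGTGAACTCCTCACAAAGCTCGACTCGGATAATCACCCGTATTAC
TCTGACGTGTCATCAAGGGCTATCTTTCCGTTGCAGGTCGGGGACCCGAATCGGCATCGT
TGA
>G0005 synthetic ORF
ATGGAGGACCGCTTCTGTACTCCAGAGTCACTTCATCCTGCTTCGTGTTGGAAGATCGCG
ATGAGACGATCCCTGCGGACAGCTTGGTGGCTAACTCCATGGCGTTGCTCTCGTGCTGCT
GTATCAGCGGATGGGCATGGCACCCTCGCAAGGTGTATTGCGGGTGATGATTCACAAGTG
AATCAAGCCTTTCCAGCCCAACCTATGTAA
>G0006 synthetic ORF
ATGTACTGCTCACGTGCCATAATCAATGTAGAAGGTGGAACGATCCAATGTGGAGGCTTC
GAGCTAGATTGTTCTGATACACGTGCAGACAAGGTCATCATTGCCCCAGGCTGTAGAAAG
GGGCCAGGCCACGGAAAAACCTGGATGCTTACCCGCCCTCAGCAGCGTTCAAGTGAAAGG
TTAGCGAGTCGATTTGGCTCAAGCTATAATTTATTTTTTGTTGTGCCTCGCCTGACAACG
TACGTCACGAAGTAA
>G0007 synthetic ORF
ATGCCAATTCCAGCTGTTAACCGAAGGAAGACACGATATTGCCCGAGGGGCTCCTTCTCT
GGCCTAGCTTCAGGGCCATACCCATCTCAACTCCCTTCCTTTAGACTCCGCTTTATCCCC
ACTTGCTACGGGTACGGACAAATGCACAACCTCTGTATGAGCTGCGTACACTGCACTTGT
AAGAAACAGATAAGTGACCTTTCACTGTGTTTAGTGACGGCCCGACGCTTCACGTAG
>G0008 synthetic ORF
ATGAAGGGATGTTGCACTGGGGCCGAAGTAGGCAGTGCACCATCAACGCTTCAAAATAAC
TTTAGCCAAACTCGGATACACATGCATCTCTCCTCGACATCCGGGAGGACCAGATTGCAG
CCGCTACGCTGGCCCGATATGCCTCGAACTATTGGAGGAAGTTCTACACCTTCGCCTTAC
AGACGAGTCACACGCGACCCCTGTGGGCCGGTTCTTTCTCATCCCCACCAAACGTGA
>G0009 synthetic ORF
ATGATGTCATTGCCGTTACCTAGATCATCGAATTCTTATGCAGCTGGCATGGTCGATGAA
TGTCTTACATTGATTCTGGAAGGATACCAAACAGGGAATTCAAGTGGCTCTTGGTTCTCC
GAGATTTTGGTAGAAAAGCTTCGAGAGGTACAGCGGTGCAGAGGCGTGTACACCGGGGCT
GGAGAAACTCTAAACCAGATAACATCGAGGAATCGCACGTCACTCGGATATACGGCCCAG
GCTTCGCACCAAGAAGTTGGTTACAGCCCGCGGCTGATGGACGGCTTTCCCACCGAACTT
CCCCATTAA
>G0010 synthetic ORF
ATGGTTAAGCGGCTCCGCGAAGACCCTGATCATCTAACGTTAATTCGCGATCCTCTGCCA
CTTACTTTCAAGAACCTAGCCTGCGAACTCATCCACGGCTCATGTCAGGTTGGCTTATCA
GCTTACGAGACGTTGAGCACAGCACCGCGCACCCCTAACGGCGATGGGTTCGCCAGGTGT
AGCAGCGACTTCGCCTGCTACTTACTTGTTTGCCAATAG
>G0011 synthetic ORF
ATGCGCACGAAGATTGTCGAACGACAAAGACGTGAAGTAGACGGAAGGGGAGGGGGCGTC
CCTCGGTTACTCTTAGTATTGCATTCACAGTTTCTTCGTACGTGCCTGTCTACGCAAGTA
AGCCCAACCCTGCATCGCGCACCCGAGCACGAGCGGAATCCACCTGATCACGCCGCCGCC
CAAGTGTGCCAGTGCCACCACAATCTCCAAACCGAGCCGTGTGTAGCAATTTGTCCAACC
AGCCATTCAGGGTTCGTCTACGTTGATTCCACCATTAGCATTGTCCTTTTCCCGCCCGCT
CAATTTATACCGGTAGGAACTCCGTCTGGACTCCCTTGA
>G0012 synthetic ORF
ATGACATCTTTTACCCGGTTATCCTGGTGGATACTGTTTGTACAGGCAAAGCACGGTGAA
CTTTTGCAAAACGGCCAAGCTTACAACAGCCTTTATGTCCCGGATGGCTTGAAGCTTCAA
TCAAACGTTAGCGATACGGATGTTCTTCAGCTTCCATCCCGACAGCTTCCTGCTCTGACT
GTACGCCTCGGCACTGAGCTCTCTCGAGTCCTATTGCCCAACTATATACTTAGCGTCGCG
AAGCGGATCCTTGTAACCTGTCTAAAGGCTTCGAGAGGCGGCCAGTTGGACATTACATCA
ACCTCGCAGCTAGGGTGA
>G0013 synthetic ORF
ATGCATCCTCCCCGGGCACCGGTACCAGTCATCTTGTCCGGGTCTCAGTCCCCTCTCGAA
TCTAATGTAGCCGTTAAGATCCCCCACCTCTCGCTCCCGGATTCGGAGTACGAAGAAATC
ACTCGATTGTTGCGCCTAGCGTGTGCATTCGATGCTAGCGTGCTGCTCTCTACGCTTGGC
GGTCTCTCGCGCTTAAGTAAGTATCTCAGTTTTGTTCTGTGGAGGTGA
>G0014 synthetic ORF
ATGTTCAAAGTAGGGCGTCCACCCGAGAAGTGCGTGGTTGTTAAGCATAGCCGCCAATTC
GTTCCCATGGGGGAAAGCCTTAAGAGGATCAGTTCCGCGCTAATTGAAGCTCTGACACGA
GCAACTTTGTTGAGCTCATGCGTCTTTCGAGTTTCCCCCTCAGATAGTGTGGTAGAGGCT
AGGCTACAGACATGTTTGAGTCCCTCGTGTTTTTCCTCGATGCCATACCTTCTCAGCGAA
CTCGCGCCACCACCACTTAAATAA
>G0015 synthetic ORF
ATGCTCCGTCTGTTTACAGACCACGTACTGACTGGAGGGCGGTATTTACCCCGATGGCGT
CGCTCCAGGCGAATAAAGGGCTCTTCCAATGTACGGATAACTATGCTGGCAGCTGATTGC
CCTCTGATATCCTCCTATCGGTACTTGGGATATTGGCGTAATCCTAAGTATATGACGGAA
CCAAAGATTGGCCCATTCGCCAGCATGCGGGCCCCGCATACGTGTCACATCGAAGTTAGA
CAGTCTCTCAAGACTGGCCTGCAGAAATCTTTACGTGATGAAACGCGCGTGGAAAATTGC
GCGGCAGGGCTCGTAAGCTTTTGCTTAATTTAG
>G0016 synthetic ORF
ATGCCTGCTAACGGACTCTACTTCCGTTCCTTTAAAACATCCGCGAAGGTCTCGCCGTTG
AATCGGTGTCGTTCCGAACATACTGCATGGTGCCCATGCGTAACGACGGGAACAAGCTGG
AGTACGGACGCTCCGCGGACGCAAAACGGAAGTACGGTAGTACAAGTCTGTCCGTACAGC
GATGAATTACCCGTCGAAAAACACGGCCAATGGATGGTAACGGACGATACCTGCTCCAAC
ACCCACCGGTTATGGGACGAAACTATTGACGTTTTGGGAACAAGTAATCTCACTCGGTCA
ATGGACCCTCACAATCTAGGGCGTTGCATTCACTTGATCAATGCTTCTGGGTGA
>G0017 synthetic ORF
ATGGCCAGTACGATGTGCGATTCTCTGTACCGGGGTCTACTGTTATTCCTTCTCCTGAGC
GAAGTTGCATCAACTCGTCATTTCGTTTTTGAAGTGTCAATGCTGACTTTCCGAACACGT
CGGATCACTGTGAATAGACGTGTATATTGCAACTTAGTGGCTTCTCCTCGGATTCCGGTT
TCACCGCGTAAACGGTGCACGGACCTAGCTTTTTTTGAAGAACCTGCGTTTCAGCGACGA
CCAACCCTTACATGCGCGCCATACTGTCAGCCTTCTCGGGCGGCGAATCGGCCTTAA
>G0018 synthetic ORF
ATGCGACTGCCTCCTGACTACCTATGTTACCTTGGTGTTCAAGCTGTGCCCTGGAAGCAT
GGTAGTACGGCAAATATACGGGGTCTCCTACCGACGTATCAGTCGATTGATGGTCGACGT
GTTAGCGTGTGTTGCGGTCAAGGCTTATTCAGCAATTTACGGACAGAACTGTCATATCAA
AATAGCAATGCGCGTAGCACGGGGGTTGTTCTGGGCATGGAAAGGGACCGGCACGGAAGG
AACGGTCAAAGGTCGCAGTTTGAAGGTGAATTTAGTTGTCCCGGTGTTAACTTCAAATTT
GGATAA
>G0019 synthetic ORF
ATGATGAATGTCGCAAATCTTCTGTTGATCAGCGTTTACCTCAATGTGGGGATGCAGTAT
AGGGATTATACGATTCGGCTAGATCCCATATGTGATCTAAGTGGCACCCAGGGCCCCCAC
TTTCCGCCTTCCTCAGGAGGAACGGGACACAAACATGTCAACAGGTGGATGTACCCGCGC
GGTCTCCATTACTATACCGTCGGCATAGTGCCGTGCAACCCAATGAGCTTATATTGGCGG
TTTTGGGCTGAGAAGAGTACCGAAAACGGTCGTTTCACCCCGACACTAATCCAGATTACC
AGGCGCTTGTAA
>G0020 synthetic ORF
ATGTATGTCGGTACCAGTACTAGACATGATCTATCTATTCGAGCACCTGCAATTGGAGGG
GTCCGCACCCGTAATGGCCTACCACCGGTCTTACAGAGGCATTGGGTACGAAAAGAAGGT
GGCGACCATGTTGACCGTGGCGTCTACATCACAAAGAGGCACAAATTGGTACTACAACGC
TAA
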