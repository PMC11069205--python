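>AluYa5_synthetic 282 bp synthetic AluYa5-like SINE consensus body
GGCCGGGCGCGGTGGTCAAACTCTTTGTGCCAAACCCTGATAGGCGGACGGCCCCTTTCTGCAGAGTAGT
CTACCCATGAGGTGGTCGCCCGGGCTTGCGCAGAGCTTCGACCTCTCCAAGCTCATAGACGTCTAGTACC
GATGAGGCCTCATGACGTCGCCTCCGGGGCTCCGCGGACACGCGGAGTTGAACGTGGCGCCCACAGGTGA
ACGGTCGAGGGTGGGCGTATCATTACGCTTCCGGTGCGCCGTGGCAACGCACAGGAGCTACGGTTGTCGG
CC
>AluYb8_synthetic synthetic AluYb8-like decoy (~18%% diverged)
GGCCGGACGCGGTGGTAATACTCTCTGTGCCAAAGCTTGATATCTGGCCGGCCCGTTTCTGCAGGGTTGT
GTACGCAGGAGGTGGTCGCCCGGGCCTGCCCATAGGTGCGAACTGTCCAAGCTCGCAGCCGTTTAGAACC
GATGTGGCCCCATGACCTCGCTTCCGGGGCTACGTGGACACGCGAACTTGAACGTTGCGGGCAGAGGCGA
ACGGTCGAGGTTGGGAGTATCATTACGCTTCCGGTGCGACTTGGTGACGCGCAGGGGCTACGGATGTCGG
CCGCCTTCG
>L1_synthetic synthetic L1-like LINE fragment decoy
CTTCGCTTAAAGAACCGTATAGAATGGTGTTGCTCCCTCTCTGTTTGCGGCCCGACTAACTTAGGTTTGA
AAACGTTCCAAGAACCCGTCGAAAACTGTAAAGATGCCAAGAAAGATCGTTCAAGTTATGTGGTAAAAAG
TGCTTGGAGGGACATTGTACAATGTAACCCTGTCCTGCTGACTTTTACAGTAACATAATTGCCAATGCGG
TTCTCCACATGGAGCTTTCGAGAAGAGGCCACTATGAGCGTAAAACTGCGTTTACACCGCCCGCTTGCGC
AACAATTTTCTCAATTATTTAAGGAGACAGTTATACAGCACTATCATACCGACGATTGAAGATAGATGCC
AAGAGGTTTAAAAATAGTTTATGTATCACACACGCTTGTGCGCCCATATTATGTGTTTACTTATTCGGGA
AACAGTGAGCTCTACAAGACATTCCTAAAAGCGATCTATTGTTTACTTTGTATTAGAAGCTTAATGTTGA
GTAAGAACGAGTTTTTGACTTTCATTCTTTGTAGGTTTTCAGACGTAGCAACCGTTAACACATGAGATTA
TAGACATATGTAAATGGGGGGCATAAATCGTTCTGTAATA
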