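gene	exon	sequence
Adgrl1	7a	TAGAAGTGGAGCAGAAAG
Adgrl1	7b	AAGTGGAGCAGAAAG
Adgrl1	9	TCTTCGTGTGCCCAGGGACCCTGCAGAAGGTGCTGGAGCCCACCTCTACACATGAGTCAGAGCATCAGTCTGGTGCATGGTGCAAGGACCCGCTGCAGGCAGGTGACCGTATCTACGTTATGCCCTGGATCCCCTACCGCACGGACACATTGACTGAATATGCCTCATGGGAGGACTATGTAGCCGCACGCCACACCACCACGTACAGACTGCCCAACCGTGTAGATGGCACTGGCTTTGTGGTCTACGATGGCGCAGTCTTCTACAACAAGGAGCGCACTCGCAACATTGTCAAATATGACCTGCGGACCCGCATCAAGAGCGGGGAAACTGTCATAAACACAGCCAACTACCACGATACCTCACCTTACCGCTGGGGAGGTAAAACCGACATTGACCTGGCAGTAGATGAGAACGGACTGTGGGTCATCTATGCAACTGAGGGCAACAATGGGCGCTTGGTGGTAAGCCAGCTCAACCCCTACACGTTGCGTTTTGAGGGCACTTGGGAAACAGGCTATGACAAGCGCTCGGCCTCCAATGCCTTCATGGTGTGCGGCGTCCTCTATGTGCTGCGTTCTGTCTATGTGGACGATGATAGCGAGGCCGCAGGCAACCGCGTGGACTATGCCTTCAACACCAATGCGAACCGTGAGGAGCCCGTCAGTCTGGCCTTCCCCAACCCCTACCAGTTCGTATCTTCTGTTGACTACAACCCCCGGGACAACCAGCTCTATGTATGGAACAACTACTTTGTTGTGCGCTATAGCCTGGAGTTTGGACCCCCAGATCCCAGTGCTG
Adgrl2	9	CTTTTTGCTCCA
Adgrl2	11a	CTCTTGTTCCCTTGGGACAGGGTCGCTCAACCATCATCCCCCTTTGTGTCTGAGGCCACTTTATCCCCTTCCAGTCTAACGCTTCGCAGAATCTCTCTGGCAGGGGAAAAATATTTGTTACAGGAGGAATTTTGGTTGTAGAGACGGCTGGAGGTGGCTTTGTCCCTCTGCTTCCGTCCTGAGGACCAGCTGCAGTGCTGCTCACGGGGCCTCGCTGGGAGGCACTGCTCGTGGTGGATATTGTGGTTTTGAACAGCTCAGCTGAAGAAGTTATTGTCACAGCTGTGGTAGGCA
Adgrl2	11b	CTCTTGTTCCCTTGGGACAGGGTCGCTCAACCATCATCCCCCTTTGTGTCTGAGGCCACTTTATCCCCTTCCAGTCTAACGCTTCGCAGAATCTCT
Adgrl2	14	CTTAAGGTAAGCCCTGCATGTCTTCTCTCGTTTTTGGAG
Adgrl2	23	CCAGGTAAGTCCGTATTATAGTAGCCATCACAAACACGGTAATTA
Adgrl2	24	TTGATAAATGGCTTATTATCTTCATAG
Adgrl2	27a	CTGAGATAAAAGACGATTCAGACTGCTTCCTCACGGTGTCATTCCACATCCTTCTTATACGGCT
Adgrl2	27b	CTTGGTTAAGGGTAGAAGTGCTATTGATGTCACCTGAGATAAAAGACGATTCAGACTGCTTCCTCACGGTGTCATTCCACATCCTTCTTATACGGCT
Adgrl2	28	CTGGCGAGTTAAACGCAGGAGCTGAAGGGGCATTGCATACAACTGTTTCAGCGAGCAGGGTGTTATAGGGGTTGTTAGTGCCGTGGGGCCGGAGAAGAGGGTTTGTTAGTAGGTAATTGCCAGTCATCC
Adgrl2	29a	CTCTAAATGATATAAATCTTGAAGATGGGCTCTCGGACCATGTGATGTCAGTC
Adgrl2	29b	CTCTAAATGATATAAATCTTGAAGATGGGCTCTCGGACCATGTGATGTCAGTCCTGTAGTAATATATTAAGATTTATGTCAC
Adgrl3	2b	CTTTTCTCCGCTAGTCTGGAGCAACACTGGACGTGGGAACGGGTTGGAGGACGAACAGGGACCGG
Adgrl3	6	GTGGCAAGCACAATGAGAGACATCCAGCCCTCGCTGCTCCACTGCGACACGCTGAGCGCAGCCCAGGAGGCGCTCTCCCTCCCAGACATCTCCTTCAGCAGCCAGCGGCAGAGCGCTCAACGGCTCATCGAGGACAGGGGCCACGCGGAGCTGCCAGAGGAGTCCGTGGACCAGGTGCCCCAGGAGCACAGATTGCAGCCCAAG
Adgrl3	9	AAGTGGAACAAAAAG
Adgrl3	15	CTTCAGAAAAGAGAGCGCTCTTGCAGAGCCTATGTCCAG
Adgrl3	24	CTATGAGGATAACAGACCCTTCATCAA
Adgrl3	30a	AGCCCTACAGAGAGACAA
Adgrl3	30b	AGCCCTACAGAGAGACAAGTATGGGAGTAAAGCTAAACATTGCATATCAAAT
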