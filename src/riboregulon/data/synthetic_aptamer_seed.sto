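# STOCKHOLM 1.0
#=GF ID synthetic_lysine_like_aptamer
#=GF CC Synthetic toy aptamer seed alignment (generated fixture, not a real Rfam seed).
apt00                 GGAAATTCCCTGGTGGGATAATCCTGTGTAACCCACACCTCCTCCATAGACGACGATATTGAGGCTGG-AAAGAATTACC
apt01                 GGAAATTCCCTCGTGGGTTACTCCAGTTTAACCCACACCTCGTCCATTGAGGACGATATGGAGGCTGGTAAAGACGTTCC
apt02                 CGAAATTCCCTCGTGGGTTACTACAGTGTAACCCACACCTCCCCCATAGACGACCATATGGGGGGTGGGAAAGAATTTCC
apt03                 GGAAATTCCCACGTGGGTTACTCAAGCGTAACCCACACCTCCTCCATAGAAGACGATATGGAGGGTGGTATAGAATTTCC
apt04                 GGAAATTCCCTCGTGGGTTCCTCCGGCTTAACCCACACCTCCTCCATAGACGTCGATATGGAGGGGGG-CAAGTATTTCC
apt05                 GGAAATTCCCTCCTGGGTTACACCAGAGTACCCCACGCCTACTCCATACACGACGATATGGAGGGTTGTAAAAAATTTCC
apt06                 GGAAATTCACTCGTGGGTTACTCCGGTTTAACCCACACCACCTCCATAGACGACGATATGGAGGGTCGTAAAGAATTTCC
apt07                 CGAAATTCCCTCCTGTGGTACCCCCGTGTAACCCACACCTCCTCCATAGACGACGATATGGAGGGTGGTAAAGAGTTTCC
apt08                 GGGAATTCCCTCGAGGGTTACTCCAGTTTAACCCACACCTCCTCCATAGACGACGATATGGAGGGTGATAAAGAATTTCC
apt09                 GGAAATTCCCTCGTTGGTTACTCC-GTGTAACCCAGACCTCCTCCATAGACGACGATATGGAGGGTGGTAAAGAATTTCC
apt10                 GTAATATCCCTCGTGGGTTACGCCAGTGTAACCCACACCTCCTCCATAGACTAGGCTATGGAGGGTGCTAAAGAATTTCC
apt11                 GGAAATTCCTTCGTGGGTTACACTCGTGTAACCCACACCTACTTCATTGACGACGATATGGAGGGTGGTAAAGAATTCTC
#=GC SS_cons          ((((((((....((((((((........))))))))....((((((((........))))))))........))))))))
//
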