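name	class	cog_id	synonyms
lysC	biosynthesis		lyC
asd	biosynthesis
dapA	biosynthesis
dapB	biosynthesis
dapD	biosynthesis
dapH	biosynthesis
ddh	biosynthesis
dapF	biosynthesis
lysA	biosynthesis
lysP	transporter	COG0833
gabP	transporter	COG0833
lysW	transporter	COG1757
yvsH	transporter	COG0531
lysX-lysY	transporter	COG0834	lysXY
kal	catabolic
kce	catabolic
amino hydrolase	other		amidohydrolase
aminotransferase	other		amino transferase
alr	other
acetyltransferase	other
cyclic beta 1-2 glucan synthetase	other
pspF3	other
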