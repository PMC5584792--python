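phylum	order	species	operon_index	genes
Firmicutes	Bacillales	Macrococcus caseolyticus	1	lysC,asd,dapA,dapB,dapD,amino hydrolase,alr,lysA
Firmicutes	Bacillales	Staphylococcus lugdunensis	1	lysC,asd,dapA,dapB,dapD
Firmicutes	Bacillales	Staphylococcus pasteuri	1	lysC,asd,dapA,dapB,dapD
Firmicutes	Bacillales	Staphylococcus epidermidis	1	lysC,asd,dapA,dapB,dapD
Firmicutes	Bacillales	Staphylococcus haemolyticus	1	lysC,asd,dapA,dapB,dapD
Firmicutes	Bacillales	Staphylococcus pseudintermedius	1	asd,dapA,dapB,dapD
Firmicutes	Bacillales	Exiguobacterium antarcticum	1	lysC,asd,dapA,dapB,dapH,aminotransferase
Firmicutes	Bacillales	Exiguobacterium sibiricum	1	lysC,asd,dapA,dapB,dapH,aminotransferase
Firmicutes	Bacillales	Geobacillus thermoglucosidasius	1	lysC,asd,dapA
Firmicutes	Lactobacillales	Lactobacillus rhamnosus	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Lactobacillus casei	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Lactobacillus buchneri	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Lactobacillus helveticus	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Lactobacillus amylovorus	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Lactobacillus acidophilus	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Lactobacillus johnsonii	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Oenococcus oeni	1	lysA,dapD,dapA,dapB,asd
Firmicutes	Lactobacillales	Leuconostoc sp.	1	lysA,dapD,dapA,dapB
Firmicutes	Lactobacillales	Leuconostoc sp.	2	alr,asd
Firmicutes	Lactobacillales	Leuconostoc kimchi	1	lysA,dapD,dapA,dapB
Firmicutes	Lactobacillales	Leuconostoc kimchi	2	alr,asd
Firmicutes	Lactobacillales	Leuconostoc citreum	1	lysA,dapD,dapA,dapB
Firmicutes	Lactobacillales	Leuconostoc citreum	2	alr,asd
Firmicutes	Lactobacillales	Leuconostoc carnosum	1	lysA,dapD,dapA,dapB
Firmicutes	Lactobacillales	Leuconostoc carnosum	2	alr,asd
Firmicutes	Lactobacillales	Leuconostoc mesenteroides	1	lysA,dapD,dapA,dapB
Firmicutes	Lactobacillales	Leuconostoc mesenteroides	2	alr,asd
Firmicutes	Clostridiales	Clostridium acidurici	1	lysA,lyC,asd,dapA,dapB
Firmicutes	Clostridiales	Peptoclostridium difficile	1	lysA,asd,dapA,dapB
Firmicutes	Clostridiales	Clostridium tetani	1	lysA,cyclic beta 1-2 glucan synthetase
Firmicutes	Clostridiales	Clostridium cellulovorans	1	lysC,lysA
Firmicutes	Clostridiales	Clostridium cellulovorans	2	dapA,dapB
Firmicutes	Clostridiales	Clostridium botulinum A	1	lysC,dapA,lysA
Firmicutes	Clostridiales	Clostridium cellulolyticum	1	dapA,dapB
Firmicutes	Clostridiales	Eubacterium eligens	1	dapA,dapB
Firmicutes	Clostridiales	Ethanoligenens harbinense	1	asd,dapA,dapB,acetyltransferase
Firmicutes	Clostridiales	Caldicellulosiruptor saccharolyticus	1	asd,dapA,dapB,acetyltransferase
Firmicutes	Clostridiales	Caldicellulosiruptor hydrothermalis	1	asd,dapA,dapB,acetyltransferase
Firmicutes	Clostridiales	Mahella australiensis	1	asd,dapA,dapB
Firmicutes	Clostridiales	Oscillibacter valericigenes	1	dapA,dapB,acetyltransferase
Gammaproteobacteria	Alteromonadales	Pseudoalteromonas haloplanktis	1	dapA,dapD,lysA,hypothetical1,hypothetical2
Gammaproteobacteria	Alteromonadales	Pseudoalteromonas sp.	1	dapA,dapD,lysA,hypothetical1,hypothetical2
Deltaproteobacteria	Bdellovibrionales	Bacteriovorax marinus	1	lysC,dapB,dapA,dapD,lysA
Thermotogae	Thermotogales	Mesotoga prima	1	asd,dapF,dapA,dapB,dapD,lysC,aminotransferase,lysA
Thermotogae	Thermotogales	Kosmotoga olearia	1	asd,dapF,dapA,dapB,dapD,lysC,aminotransferase
Thermotogae	Thermotogales	Thermosipho melanesiensis	1	asd,dapF,dapA,dapB,dapD,lysC,aminotransferase
Thermotogae	Thermotogales	Thermosipho africanus	1	asd,dapF,dapA,dapB,dapD,lysC,aminotransferase
Thermotogae	Thermotogales	Marinitoga piezophila	1	asd,lysA,dapA,dapB,dapD,lysC,aminotransferase,amidohydrolase
Thermotogae	Thermotogales	Petrotoga mobilis	1	dapA,dapB,dapD,lysC,aminotransferase,amidohydrolase
Thermotogae	Thermotogales	Thermotoga neapolitana	1	asd,dapF,dapA,dapB,dapD,lysC,lysA,amidohydrolase
Thermotogae	Thermotogales	Thermotoga maritima	1	asd,dapF,dapA,dapB,dapD,lysC,lysA,amidohydrolase
Thermotogae	Thermotogales	Thermotoga sp.	1	asd,dapF,dapA,dapB,dapD,lysC,lysA,amidohydrolase
Thermotogae	Thermotogales	Thermotoga petrophila	1	asd,dapF,dapA,dapB,dapD,lysC,lysA,amidohydrolase
Thermotogae	Thermotogales	Thermotoga naphthophila	1	asd,dapF,dapA,dapB,dapD,lysC,lysA,amidohydrolase
Fusobacteria	Fusobacterales	Sebaldella termitidis	1	lysA,lysC,dapF,hypothetical,dapA,asd
Fusobacteria	Fusobacterales	Leptotrichia buccalis	1	lysA,lysC,dapF
Actinobacteria	Coriobacteriales	Atopobium parvulum	1	lysA,dapA,dapB
Actinobacteria	Coriobacteriales	Slackia heliotrinireducens	1	lysA,dapA,dapB,dapD
Acidobacteria	Solibacterales	Candidatus Solibacter usitatus	1	asd,lysC
Firmicutes	Clostridiales	Clostridium sticklandii	1	kal,kce
Firmicutes	Thermoanaerobacterales	Thermoanaerobacter tengcongensis	1	pspF3,kal,kce
Firmicutes	Thermoanaerobacterales	Thermoanaerobacter wiegelii	1	pspF3,kal,kce
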