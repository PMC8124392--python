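dub,gene,description,log2_fc
USP1,BCOR,BCL-6 corepressor,2.43
USP1,PCNA,Proliferating cell nuclear antigen,1.49
USP1,GLUL,Glutamine synthetase,1.12
USP7,TTK,Dual specificity protein kinase TTK,2.33
USP7,GABPA,GA-binding protein alpha chain,1.66
USP7,RPL29,60S ribosomal protein L29,1.61
USP7,RNF2,E3 ubiquitin-protein ligase RING2,1.54
USP7,CREB1,Cyclic AMP-responsive element-binding protein 1,1.44
USP7,MARCKS,Myristoylated alanine-rich C-kinase substrate,1.21
USP9X,RNF10,RING finger protein 10,3.94
USP9X,RPS25,40S ribosomal protein S25,3.59
USP9X,CCND2,G1/S-specific cyclin-D2,3.32
USP9X,TMEM259,Membralin,3.00
USP9X,AAMP,Angio-associated migratory cell protein,2.77
USP9X,VHL,Von Hippel-Lindau disease tumor suppressor,2.18
USP9X,SEPT6,Septin-6,2.17
USP9X,MICALL1,MICAL-like protein 1,2.14
USP9X,CCDC124,Coiled-coil domain-containing protein 124,1.95
USP9X,CORO7,Coronin-7,1.91
USP9X,DLG3,Disks large homolog 3,1.82
USP9X,RPL13A,60S ribosomal protein L13a,1.71
USP9X,TCP11L2,T-complex protein 11-like protein 2,1.56
USP9X,GPRASP2,G-protein coupled receptor-associated sorting protein 2,1.25
USP9X,ARAF,Serine/threonine-protein kinase A-Raf,1.20
USP9X,GNA12,Guanine nucleotide-binding protein subunit alpha-12,1.19
USP9X,ZNF598,Zinc finger protein 598,1.19
USP9X,ZC3H15,Zinc finger CCCH domain-containing protein 15,1.08
USP9X,CEP170,Centrosomal protein of 170 kDa,1.06
USP9X,PDIA4,Protein disulfide-isomerase A4,1.00
USP11,RPS2,40S ribosomal protein S2,4.17
USP11,UBE2L3,Ubiquitin-conjugating enzyme E2 L3,2.15
USP11,RPS7,40S ribosomal protein S7,1.33
USP42,SLC20A1,Sodium-dependent phosphate transporter 1,4.09
USP42,WARS,"Tryptophan--tRNA ligase, cytoplasmic",3.86
USP42,CUL2,Cullin-2,2.94
USP42,UBR7,Putative E3 ubiquitin-protein ligase UBR7,2.86
USP42,CPD,Carboxypeptidase D,2.31
USP42,ARHGAP17,Rho GTPase-activating protein 17,2.30
USP42,SETD3,Histone-lysine N-methyltransferase setd3,2.10
USP42,GTF2H1,General transcription factor IIH subunit 1,2.04
USP42,CORO1C,Coronin-1C,1.95
USP42,HMOX1,Heme oxygenase 1,1.69
USP42,PRKAR2A,cAMP-dependent protein kinase type II-alpha regulatory subunit,1.65
USP42,DNAJC21,DnaJ homolog subfamily C member 21,1.52
USP42,FUBP3,Far upstream element-binding protein 3,1.40
USP42,PES1,Pescadillo homolog,1.38
USP42,SMARCD2,SWI/SNF-related matrix-associated actin-dependent regulator of chromatin subfamily D member 2,1.36
USP42,LSR,Lipolysis-stimulated lipoprotein receptor,1.26
USP42,IFT81,Intraflagellar transport protein 81 homolog,1.25
USP42,RAD50,DNA repair protein RAD50,1.23
USP42,RNF2,E3 ubiquitin-protein ligase RING2,1.11
USP42,PJA2,E3 ubiquitin-protein ligase Praja-2,1.10
USP42,PSMC6,26S protease regulatory subunit 10B,1.07
USP42,BUB3,Mitotic checkpoint protein BUB3,1.06
USP42,BTBD2,BTB/POZ domain-containing protein 2,1.05
USP42,FABP5,"Fatty acid-binding protein, epidermal",1.02
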