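peptide	protein_name
GVIEEAISEINLELEER	Excinuclease ABC subunit B
QKEIFIEFEEDGEYMYFLFHRDK	Hypothetical protein
EIFDGEMGIYAIHAGVECGIIK	Aminoacyl-histidine dipeptidase
VYSGVTINNVDVSGLSR	Vancomycin B-type resistance protein VanW
NFETGTLGDLIK	DUF4214 domain-containing protein
EMMDQPEFK	DUF4214 domain-containing protein
LNEEIKEIVAR	Type I restriction-modification system subunit M
LVVAVSNAHYIEK	PolC-type DNA polymerase III
DYKEIEDVIKEIYK	PolC-type DNA polymerase III
VADSMFLNFWWTTNR	Endo-beta-N-acetylglucosaminidase
EKTDGVELQVGANK	Flagellar biosynthesis protein FliC
DRNLDVTISIVDR	Flagellar biosynthesis protein FliC
AILSEGVELIK	Protein kinase
KLEKESNYVLK	DNA ligase (NAD(+)) LigA
EKIEVMPVEYEK	Carboxyl-terminal processing protease
SLVEVPSDNDLEK	ATP-dependent protease, Lon family
RSMVEKNGK	Fe-S cluster assembly protein SufB
KSGLDQLIVK	GTP-binding protein YchF
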