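accession	annotation	best_score	go_categorized	ssom	isom
PFX12726.1	Retrovirus-related Pol polyprotein from transposon 17.6	340.80	false	false	true
PFX12813.1	Hypothetical protein AWC38_SpisGene23165	337.40	false	false	true
PFX13778.1	Sacsin	267.80	false	false	true
PFX14205.1	Proto-oncogene tyrosine-protein kinase receptor Ret, partial	336.70	true	false	true
PFX15740.1	Protein FAM208A	373.20	false	true	true
PFX16398.1	Hypothetical protein AWC38_SpisGene19330	273.10	false	false	true
PFX18785.1	Mucin-4	449.50	true	false	true
PFX26597.1	Complement C3	283.10	true	false	true
PFX26751.1	Transmembrane protease serine 9	244.20	true	false	true
PFX27832.1	Poly [ADP-ribose] polymerase 11	320.10	true	false	true
PFX30831.1	Hypothetical protein AWC38_SpisGene4366	322.20	false	false	true
PFX30903.1	Hypothetical protein AWC38_SpisGene4292	548.90	false	false	true
PFX31810.1	Nidogen-2	286.20	true	false	true
XP_022783323.1	Phosphopantothenoylcysteine decarboxylase subunit VHS3-like	406.60	true	false	true
XP_022786582.1	Synapsin-2-like isoform X2	320.50	true	true	true
XP_022799089.1	CUB domain-containing protein-like isoform X2	699.70	false	false	true
XP_022804012.1	EGF and laminin G domain-containing protein-like	384.10	true	false	true
XP_022779720.1	Vitellogenin-like	416.00	true	false	true
XP_022780303.1	LOW QUALITY PROTEIN: uncharacterized protein LOC111321626	353.60	true	true	false
XP_022780690.1	Skeletal aspartic acid-rich protein 2-like	723.60	true	false	true
XP_022780694.1	CUB and peptidase domain-containing protein 2-like	285.80	true	true	true
XP_022782398.1	Skeletal aspartic acid-rich protein 1-like	709.80	false	true	true
XP_022783044.1	Uncharacterized protein LOC111323869	283.60	false	false	true
XP_022783415.1	Coadhesin-like isoform X3	411.20	true	false	true
XP_022783952.1	Collagenase 3-like	262.90	true	false	true
XP_022784623.1	Cation channel sperm-associated protein subunit beta-like	328.40	true	false	true
XP_022786918.1	Major yolk protein-like isoform X2	476.50	true	false	true
XP_022788227.1	Hephaestin-like protein	539.80	true	false	true
XP_022788730.1	Chymotrypsin-like elastase family member 1	264.80	true	false	true
XP_022789591.1	Endothelin-converting enzyme 1-like isoform X2	94.10	true	false	true
XP_022789932.1	MAGUK p55 subfamily member 7-like	313.70	true	false	true
XP_022790441.1	PHD finger protein 21A-like	277.90	true	false	true
XP_022792212.1	Ras-like protein 3	289.90	true	false	true
XP_022794122.1	Galaxin-like isoform X2	309.40	false	false	true
XP_022794351.1	Mammalian ependymin-related protein 1-like	324.80	true	false	true
XP_022794736.1	MAM and LDL-receptor class A domain-containing protein 2-like	472.20	false	false	true
XP_022796981.1	Uncharacterized skeletal organic matrix protein 8-like	664.40	false	false	true
XP_022796982.1	Uncharacterized protein LOC111335364	609.30	false	false	true
XP_022798902.1	Low-density lipoprotein receptor-related protein 8-like	257.10	true	false	true
XP_022799541.1	Uncharacterized protein LOC111337489	461.10	true	false	true
XP_022803524.1	Digestive cysteine proteinase 1-like	262.20	true	false	true
XP_022803808.1	Deleted in malignant brain tumors 1 protein-like	344.70	true	false	true
XP_022803872.1	Spore wall protein 2-like isoform X3	338.60	false	false	true
XP_022803894.1	Uncharacterized protein LOC111341206	390.70	true	false	true
XP_022804785.1	Thioredoxin reductase 1, cytoplasmic-like	337.00	true	false	true
XP_022805470.1	Uncharacterized protein LOC111342641	256.10	false	false	true
XP_022806326.1	ZP domain-containing protein-like	393.90	true	false	true
XP_022806664.1	Protein lingerer-like	250.10	true	false	true
XP_022806928.1	SLIT-ROBO Rho GTPase-activating protein 1-like	309.10	false	false	true
XP_022807143.1	Condensin-2 complex subunit D3-like	278.10	true	false	true
XP_022807256.1	Uncharacterized protein LOC111344300	280.40	true	false	true
XP_022807807.1	Uncharacterized protein LOC111344812	365.30	true	false	true
XP_022808163.1	Uncharacterized protein LOC111345150	310.20	false	false	true
XP_022808576.1	Uncharacterized protein LOC111345553 isoform X2	320.10	true	false	true
XP_022809269.1	Microtubule-associated tumor suppressor 1 homolog isoform X1	259.20	true	false	true
XP_022809270.1	Microtubule-associated tumor suppressor 1 homolog isoform X2	256.40	false	false	true
XP_022810585.1	Von Willebrand factor D and EGF domain-containing protein-like, partial	298.80	false	false	true
XP_022778254.1	Uncharacterized protein LOC111319781	250.70	true	false	true
XP_022778283.1	Uncharacterized protein LOC111319816, partial	508.10	false	true	true
ACE95141.1	Carbonic anhydrase	495.20	true	true	true
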