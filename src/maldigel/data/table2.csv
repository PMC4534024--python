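accession,control_count,case_count,full_name,uniprot_accessions
sw:ENOA_HUMAN,0,33,"Alpha enolase (EC 4.2.1.11) (2-phospho-D-glycerate hydro-lyase) (non-neural enolase) (NNE) (enolase 1) (phosphopyruvate hydratase)",P06733 Q16704 Q9UM55
sw:K1CQ_HUMAN,0,17,"Keratin, type I cytoskeletal 17 (cytokeratin 17) (K17) (CK 17) (39.1)",Q04695
sw:G3P2_HUMAN,0,12,"Glyceraldehyde 3-phosphate dehydrogenase, liver (EC 1.2.1.12) (GAPDH)",P04406
sw:FSC1_HUMAN,0,11,"Fascin (singed-like protein) (55 kDa actin bundling protein) (p55)",Q16658 Q96IC5 Q9BRF1
sw:HBA_HUMAN,0,11,Hemoglobin alpha chain,P01922
sw:MASP_HUMAN,0,11,Maspin precursor (protease inhibitor 5),P36952
sw:NDR1_HUMAN,0,11,"NDRG1 protein (N-myc downstream-regulated gene 1 protein) (differentiation-related gene 1 protein) (DRG1) (reducing agents and tunicamycin-responsive protein) (RTP) (nickel-specific induction protein CAP43) (RIT42)",Q92597 O15207 Q9NYR6 Q9UK29
sw:PGK1_HUMAN,0,11,Phosphoglycerate kinase 1 (EC 2.7.2.3) (primer recognition protein 2) (PRP 2),P00558
sw:PLSL_HUMAN,0,10,L-plastin (lymphocyte cytosolic protein 1) (LCP-1) (LC64P),P13796
sw:SCC1_HUMAN,0,10,Squamous cell carcinoma antigen 1 (SCCA-1) (protein T4-A),P29508 Q96J21
sw:TYPH_HUMAN,0,10,"Thymidine phosphorylase precursor (EC 2.4.2.4) (TdRPase) (TP) (platelet-derived endothelial cell growth factor) (PD-ECGF) (gliostatin)",P19971 Q13390 Q8WVB7
sw:CATA_HUMAN,0,8,Ccatalase (EC 1.11.1.6),P04040
humangp:HCHR12-007545,0,6,"tr:q7z793: keratin 6 L was used to identify this gene current sequence which covers 100.0% of the above current sequence which is 100.0% identical to the above sequence",HCHR12-007545
sw:TBB5_HUMAN,0,6,Tubulin beta-5 chain,P05218 Q8WUC1 Q9CY33
sw:TBBX_HUMAN,0,6,Tubulin beta-5 chain (tubulin 5 beta),P04350
sw:TKT_HUMAN,0,6,Transketolase (EC 2.2.1.1) (TK),P29401
sw:TAL1_HUMAN,0,5,Transaldolase (EC 2.2.1.2),P37837 O00751
sw:VINC_HUMAN,0,5,Vinculin (metavinculin),P18206 Q16450
sw:CAH2_HUMAN,0,4,Carbonic anhydrase II (EC 4.2.1.1) (carbonate dehydratase II) (CA-II) (carbonic anhydrase C),P00918 Q96ET9
sw:CERU_HUMAN,0,4,Ceruloplasmin precursor (EC 1.16.3.1) (ferroxidase),P00450 Q14063
sw:GTO1_HUMAN,0,4,Glutathione transferase omega 1 (EC 2.5.1.18) (GSTO 1-1),P78417
sw:ITH4_HUMAN,0,4,"Inter-alpha-trypsin inhibitor heavy chain H4 precursor (ITI heavy chain H4) (inter-alpha-inhibitor heavy chain 4) (inter-alpha-trypsin inhibitor family heavy chain-related protein) (IHRP) (plasma kallikrein-sensitive glycoprotein 120) (PK-120) (GP120) (Pro1851) [contains: GP57]",Q14624 Q15135 Q9P190 Q9UQ54
sw:OTB1_HUMAN,0,4,"Ubiquitin thiolesterase protein OTUB1 (EC 3.4.-.-) (otubain 1) (OTU domain-containing ubiquitin aldehyde-binding protein 1) (ubiquitin-specific processing protease OTUB1) (deubiquitinating enzyme OTUB1) (HSPC263)",Q96FW1 Q96II3 Q9NXQ4 Q9P0B8
sw:PLST_HUMAN,0,4,T-plastin,P13797
sw:SAHH_HUMAN,0,4,Adenosylhomocysteinase (EC 3.3.1.1) (s-adenosyl-l-homocysteine hydrolase) (AdoHcyase),P23526 Q96A36
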