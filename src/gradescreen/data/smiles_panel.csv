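identifier,name,smiles
panel_001,aspirin,CC(=O)Oc1ccccc1C(=O)O
panel_002,paracetamol,CC(=O)Nc1ccc(O)cc1
panel_003,ibuprofen,CC(C)Cc1ccc(cc1)C(C)C(=O)O
panel_004,caffeine,Cn1cnc2c1c(=O)n(C)c(=O)n2C
panel_005,naproxen,COc1ccc2cc(C(C)C(=O)O)ccc2c1
panel_006,diazepam,CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21
panel_007,lidocaine,CCN(CC)CC(=O)Nc1c(C)cccc1C
panel_008,procaine,CCN(CC)CCOC(=O)c1ccc(N)cc1
panel_009,atenolol,CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
panel_010,propranolol,CC(C)NCC(O)COc1cccc2ccccc12
panel_011,metoprolol,COCCc1ccc(OCC(O)CNC(C)C)cc1
panel_012,nicotine,CN1CCCC1c1cccnc1
panel_013,theophylline,Cn1c(=O)c2[nH]cnc2n(C)c1=O
panel_014,warfarin,CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
panel_015,fluconazole,OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F
panel_016,olaparib,C1CC1C(=O)N2CCN(CC2)C(=O)C3=C(C=CC(=C3)CC4=NNC(=O)C5=CC=CC=C54)F
panel_017,LY294002,C1COCCN1C2=CC(=O)C3=C(O2)C(=CC=C3)C4=CC=CC=C4
panel_018,celecoxib,Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1
panel_019,benzamide,NC(=O)c1ccccc1
panel_020,morpholinoyl-indole,O=C(N1CCOCC1)c1cc2ccccc2[nH]1
panel_021,pyridinyl-piperazine urea,O=C(Nc1ccccn1)N1CCN(C)CC1
panel_022,sulfanilamide,Nc1ccc(S(N)(=O)=O)cc1
panel_023,isoniazid,NNC(=O)c1ccncc1
panel_024,benzimidazolyl cyclopropanecarboxamide,O=C(Nc1ccc2[nH]cnc2c1)C1CC1
panel_025,anisyl-piperazine,COc1ccccc1N1CCNCC1
panel_026,quinoline-2-carboxamide,NC(=O)c1ccc2ccccc2n1
panel_027,dimethylphenyloxazole,Cc1oc(-c2ccccc2)nc1C
panel_028,morpholino-benzamide,O=C(c1ccccc1)N1CCOCC1
panel_029,tolyl-piperidine,Cc1ccc(C2CCNCC2)cc1
panel_030,fluorophenyl-pyrazole,Fc1ccc(-n2cccn2)cc1
panel_031,maleimide-phenyl,O=C1C=CC(=O)N1c1ccccc1
panel_032,menadione,CC1=CC(=O)c2ccccc2C1=O
panel_033,dopamine,NCCc1ccc(O)c(O)c1
panel_034,epinephrine,CNCC(O)c1ccc(O)c(O)c1
panel_035,quercetin,O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12
panel_036,curcumin,COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O
panel_037,catechol-morpholinoamide,O=C(N1CCOCC1)c1ccc(O)c(O)c1
panel_038,nitrobenzamide,O=C(N)c1ccc([N+](=O)[O-])cc1
panel_039,rhodanine,O=C1CSC(=S)N1
panel_040,benzylidene-rhodanine,O=C1C(=Cc2ccccc2)SC(=S)N1
panel_041,chloramphenicol,OCC(NC(=O)C(Cl)Cl)C(O)c1ccc([N+](=O)[O-])cc1
panel_042,hydroquinone,Oc1ccc(O)cc1
panel_043,azobenzene,c1ccc(/N=N/c2ccccc2)cc1
panel_044,phenyl-acrylamide,C=CC(=O)Nc1ccccc1
panel_045,phenylthiourea,NC(=S)Nc1ccccc1
panel_046,oleamide,CCCCCCCC/C=C\CCCCCCCC(N)=O
panel_047,stearic acid,CCCCCCCCCCCCCCCCCC(=O)O
panel_048,stearyl laurate,CCCCCCCCCCCCCCCCCCOC(=O)CCCCCCCCCCC
panel_049,octaethylene glycol,OCCOCCOCCOCCOCCOCCOCCOCCO
panel_050,dialkylamine C28,CCCCCCCCCCCCCCCCNCCCCCCCCCCCC
panel_051,polyprenyl chain,CC(C)=CCCC(C)=CCCC(C)=CCCC(C)=CCCC(C)=CCCC(C)=CC
panel_052,pentadecyl-catechol,CCCCCCCCCCCCCCCc1ccc(O)c(O)c1
panel_053,pentadecyl-quinone,CC1=CC(=O)C(CCCCCCCCCCCCCCC)=CC1=O
panel_054,dodecyl-dinitrophenol,CCCCCCCCCCCCc1cc([N+](=O)[O-])cc([N+](=O)[O-])c1O
panel_055,tetrapeptide acid,CC(NC(=O)C(N)CC(=O)O)C(=O)NC(CC(=O)O)C(=O)NC(Cc1ccccc1)C(=O)NC(CO)C(=O)O
panel_056,bis-rhodanine stilbenoid,O=C1C(=Cc2ccc(/C=C3\SC(=S)NC3=O)cc2)SC(=S)N1
panel_057,catechin gallate analog,Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(OC(=O)c1cc(O)c(O)c(O)c1)C2
panel_058,triacontane,CCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
panel_059,tannin fragment,O=C(OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1)c1cc(O)c(O)c(O)c1
panel_060,doxorubicin,COc1cccc2c1C(=O)c1c(O)c3c(c(O)c1C2=O)CC(O)(C(C)=O)CC3OC1CC(N)C(O)C(C)O1
panel_061,cholesteryl laurate,CC(C)CCCC(C)C1CCC2C3CC=C4CC(OC(=O)CCCCCCCCCCC)CCC4(C)C3CCC12C
panel_062,hexapeptide acid,NC(CC(=O)O)C(=O)NC(CCCNC(N)=N)C(=O)NC(Cc1ccccc1)C(=O)NC(CO)C(=O)NC(CC(=O)O)C(=O)NC(CCCCN)C(=O)O
panel_063,palmitoyl tetrapeptide,CCCCCCCCCCCCCCCC(=O)NC(CC(=O)O)C(=O)NC(CCCNC(N)=N)C(=O)NC(Cc1ccc(O)c(O)c1)C(=O)NC(CO)C(=O)O
panel_064,trigalloyl glycoside,OC1OC(COC(=O)c2cc(O)c(O)c(O)c2)C(OC(=O)c2cc(O)c(O)c(O)c2)C(O)C1OC(=O)c1cc(O)c(O)c(O)c1
panel_065,eicosyl-dinitrophenol,O=[N+]([O-])c1cc(CCCCCCCCCCCCCCCCCCCC)cc([N+](=O)[O-])c1O
panel_066,hexadecaethylene glycol,OCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOCCO
panel_067,dodecyl-bis-rhodanine,O=C1C(=Cc2ccc(CCCCCCCCCCCC/C=C3\SC(=S)NC3=O)cc2)SC(=S)N1
panel_068,cardiotonic steroid glycoside,CC1CCC2(O)CCC3(C)C(CCC4C3CC(O)C3(C)C(C(=O)OC5CC(O)C(O)C(C)O5)CCC43O)C2C1
panel_069,alkyl quinone-rhodanine,O=C1C=CC(=O)C(c2cc(O)c(O)c(/C=C3\SC(=S)NC3=O)c2)=C1CCCCCCCCCCCCCC
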