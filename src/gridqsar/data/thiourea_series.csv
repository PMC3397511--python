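record,f1,f2,f3,f4
scaffold,thiourea_sub,Nc1ncc({rp})nc1NC(=S)N{rn},,
scaffold,thiourea_h,Nc1nccnc1NC(=S)N{rn},,
rgroup,H,rp,,
rgroup,Cl,rp,Cl,
rgroup,Me,rp,C,
rgroup,Et,rp,CC,
rgroup,n-Pr,rp,CCC,
rgroup,n-Bu,rp,CCCC,
rgroup,c-Pr,rp,C7CC7,
rgroup,Ph,rn,c5ccccc5,
rgroup,Et,rn,CC,
rgroup,i-Pr,rn,C(C)C,
rgroup,t-Bu,rn,C(C)(C)C,
rgroup,c-Pr,rn,C5CC5,
rgroup,c-Pentyl,rn,C5CCCC5,
rgroup,c-Heptanyl,rn,C5CCCCCC5,
rgroup,Bn,rn,Cc5ccccc5,
rgroup,MeOCH2CH2,rn,CCOC,
rgroup,Benzoyl,rn,C(=O)c5ccccc5,
rgroup,1-Naphthyl,rn,c5cccc6ccccc56,
rgroup,4-Me,rn,c5ccc(C)cc5,
rgroup,4-Cl,rn,c5ccc(Cl)cc5,
rgroup,4-MeO,rn,c5ccc(OC)cc5,
rgroup,4-i-Pr,rn,c5ccc(C(C)C)cc5,
rgroup,4-t-Bu,rn,c5ccc(C(C)(C)C)cc5,
rgroup,4-Br,rn,c5ccc(Br)cc5,
rgroup,4-NO2,rn,c5ccc([N+](=O)[O-])cc5,
rgroup,4-CN,rn,c5ccc(C#N)cc5,
rgroup,4-BnO,rn,c5ccc(OCc6ccccc6)cc5,
rgroup,4-Ac,rn,c5ccc(C(C)=O)cc5,
rgroup,4-EtOC(=O)-,rn,c5ccc(C(=O)OCC)cc5,
rgroup,4-NMe2,rn,c5ccc(N(C)C)cc5,
rgroup,4-(Morphorin-1-yl),rn,c5ccc(N6CCOCC6)cc5,
rgroup,4-AcNH-,rn,c5ccc(NC(C)=O)cc5,
rgroup,4-NH2,rn,c5ccc(N)cc5,
rgroup,4-BnOC(=O)NH-,rn,c5ccc(NC(=O)OCc6ccccc6)cc5,
rgroup,2-Me,rn,c5ccccc5C,
rgroup,2-Cl,rn,c5ccccc5Cl,
rgroup,2-MeO,rn,c5ccccc5OC,
rgroup,2-F,rn,c5ccccc5F,
rgroup,2-MeS,rn,c5ccccc5SC,
rgroup,3-Me,rn,c5cccc(C)c5,
rgroup,3-Cl,rn,c5cccc(Cl)c5,
rgroup,3-MeO,rn,c5cccc(OC)c5,
rgroup,"2,4-Di-MeO",rn,c5ccc(OC)cc5OC,
rgroup,"2,4-Di-Cl",rn,c5ccc(Cl)cc5Cl,
rgroup,"3,5-Di-Cl",rn,c5cc(Cl)cc(Cl)c5,
rgroup,MeOC(=O)NH-,rn,c5ccc(NC(=O)OC)cc5,
rgroup,EtOC(=O)NH-,rn,c5ccc(NC(=O)OCC)cc5,
rgroup,n-BuOC(=O)NH-,rn,c5ccc(NC(=O)OCCCC)cc5,
rgroup,i-BuOC(=O)NH-,rn,c5ccc(NC(=O)OCC(C)C)cc5,
rgroup,t-BuOC(=O)NH-,rn,c5ccc(NC(=O)OC(C)(C)C)cc5,
rgroup,i-BuOC(=O)N(Ph)-,rn,c5ccc(N(c6ccccc6)C(=O)OCC(C)C)cc5,
rgroup,MeNHC(=O)NH-,rn,c5ccc(NC(=O)NC)cc5,
rgroup,t-BuNHC(=O)NH-,rn,c5ccc(NC(=O)NC(C)(C)C)cc5,
rgroup,PhOC(=O)NH-,rn,c5ccc(NC(=O)Oc6ccccc6)cc5,
rgroup,EtOC(=O)N(Me)-,rn,c5ccc(N(C)C(=O)OCC)cc5,
rgroup,t-BuOC(=O)O-,rn,c5ccc(OC(=O)OC(C)(C)C)cc5,
rgroup,EtC(=O)NH-,rn,c5ccc(NC(=O)CC)cc5,
rgroup,n-PrC(=O)NH-,rn,c5ccc(NC(=O)CCC)cc5,
rgroup,n-BuC(=O)NH-,rn,c5ccc(NC(=O)CCCC)cc5,
rgroup,BnC(=O)NH-,rn,c5ccc(NC(=O)Cc6ccccc6)cc5,
rgroup,PhC(=O)NH-,rn,c5ccc(NC(=O)c6ccccc6)cc5,
rgroup,3-NHC(=O)NH-4,rn,c5cc6[nH]c(=O)[nH]c6cc5,
rgroup,3-CH2C(=O)NH-4,rn,c5cc6CC(=O)Nc6cc5,
rgroup,3-SC(=O)NH-4,rn,c5cc6SC(=O)Nc6cc5,
rgroup,3-NHC(=O)O-4,rn,c5cc6NC(=O)Oc6cc5,
rgroup,4-(2-oxo-oxazolidin-5-yl),rn,c5ccc(C6CNC(=O)O6)cc5,
rgroup,4-(2-oxo-oxazolidin-4-yl),rn,c5ccc(C6NC(=O)OC6)cc5,
rgroup,4-((2-oxo-oxazolidin-5-yl)methyl),rn,c5ccc(CC6CNC(=O)O6)cc5,
rgroup,4-(2-oxo-3H-oxazol-5-yl),rn,c5ccc(C6=CNC(=O)O6)cc5,
rgroup,4-(2-oxo-3H-oxazol-4-yl),rn,c5ccc(C6=COC(=O)N6)cc5,
compound,1,thiourea_sub,Cl,Ph
compound,2,thiourea_sub,Cl,Et
compound,3,thiourea_sub,Cl,i-Pr
compound,4,thiourea_sub,Cl,t-Bu
compound,5,thiourea_sub,Cl,c-Pr
compound,6,thiourea_sub,Cl,c-Pentyl
compound,7,thiourea_sub,Cl,c-Heptanyl
compound,8,thiourea_sub,Cl,Bn
compound,9,thiourea_sub,Cl,MeOCH2CH2
compound,10,thiourea_sub,Cl,Benzoyl
compound,11,thiourea_sub,Cl,1-Naphthyl
compound,12,thiourea_h,H,Ph
compound,13,thiourea_sub,Me,Ph
compound,14,thiourea_sub,Et,Ph
compound,15,thiourea_sub,n-Pr,Ph
compound,16,thiourea_sub,c-Pr,Ph
compound,17,thiourea_sub,Cl,4-Me
compound,18,thiourea_sub,Cl,4-Cl
compound,19,thiourea_sub,Cl,4-MeO
compound,20,thiourea_sub,Cl,4-i-Pr
compound,21,thiourea_sub,Cl,4-t-Bu
compound,22,thiourea_sub,Cl,4-Br
compound,23,thiourea_sub,Cl,4-NO2
compound,24,thiourea_sub,Cl,4-CN
compound,25,thiourea_sub,Cl,4-BnO
compound,26,thiourea_sub,Cl,4-Ac
compound,27,thiourea_sub,Cl,4-EtOC(=O)-
compound,28,thiourea_sub,Cl,4-NMe2
compound,29,thiourea_sub,Cl,4-(Morphorin-1-yl)
compound,30,thiourea_sub,Cl,4-AcNH-
compound,31,thiourea_sub,Cl,4-NH2
compound,32,thiourea_sub,Cl,4-BnOC(=O)NH-
compound,33,thiourea_sub,Cl,2-Me
compound,34,thiourea_sub,Cl,2-Cl
compound,35,thiourea_sub,Cl,2-MeO
compound,36,thiourea_sub,Cl,2-F
compound,37,thiourea_sub,Cl,2-MeS
compound,38,thiourea_sub,Cl,3-Me
compound,39,thiourea_sub,Cl,3-Cl
compound,40,thiourea_sub,Cl,3-MeO
compound,41,thiourea_sub,Cl,"2,4-Di-MeO"
compound,42,thiourea_sub,Cl,"2,4-Di-Cl"
compound,43,thiourea_sub,Cl,"3,5-Di-Cl"
compound,44,thiourea_sub,Cl,MeOC(=O)NH-
compound,45,thiourea_sub,Cl,EtOC(=O)NH-
compound,46,thiourea_sub,Cl,n-BuOC(=O)NH-
compound,47,thiourea_sub,Cl,i-BuOC(=O)NH-
compound,48,thiourea_sub,Cl,t-BuOC(=O)NH-
compound,49,thiourea_sub,Cl,i-BuOC(=O)N(Ph)-
compound,50,thiourea_sub,Cl,MeNHC(=O)NH-
compound,51,thiourea_sub,Cl,t-BuNHC(=O)NH-
compound,52,thiourea_sub,Me,t-BuOC(=O)NH-
compound,53,thiourea_sub,Me,PhOC(=O)NH-
compound,54,thiourea_sub,Me,EtOC(=O)N(Me)-
compound,55,thiourea_sub,Me,t-BuOC(=O)O-
compound,56,thiourea_sub,Me,EtC(=O)NH-
compound,57,thiourea_sub,Me,n-PrC(=O)NH-
compound,58,thiourea_sub,Me,n-BuC(=O)NH-
compound,59,thiourea_sub,Me,BnC(=O)NH-
compound,60,thiourea_sub,Me,PhC(=O)NH-
compound,61,thiourea_sub,Cl,3-NHC(=O)NH-4
compound,62,thiourea_sub,Cl,3-CH2C(=O)NH-4
compound,63,thiourea_sub,Cl,3-SC(=O)NH-4
compound,64,thiourea_sub,Cl,3-NHC(=O)O-4
compound,65,thiourea_sub,Et,4-(2-oxo-oxazolidin-5-yl)
compound,66,thiourea_sub,n-Pr,4-(2-oxo-oxazolidin-4-yl)
compound,67,thiourea_sub,c-Pr,4-((2-oxo-oxazolidin-5-yl)methyl)
compound,68,thiourea_sub,n-Pr,4-(2-oxo-3H-oxazol-5-yl)
compound,69,thiourea_sub,n-Bu,4-(2-oxo-3H-oxazol-4-yl)
compound,70,thiourea_sub,c-Pr,4-(2-oxo-3H-oxazol-5-yl)
compound,71,thiourea_sub,c-Pr,4-(2-oxo-3H-oxazol-4-yl)
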