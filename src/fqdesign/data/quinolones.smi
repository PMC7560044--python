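# Synthetic repository fixture: public structures of the 16 quinolones (SMILES<TAB>id)
CCn1cc(C(=O)O)c(=O)c2ccc(C)nc21	Nalidixic acid
CCn1cc(C(=O)O)c(=O)c2cc3c(cc21)OCO3	Oxolinic acid
CCn1nc(C(=O)O)c(=O)c2cc3c(cc21)OCO3	Cinoxacin
CCn1cc(C(=O)O)c(=O)c2ccc(-c3ccncc3)cc21	Rosoxacin
CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21	Norfloxacin
CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)nc21	Enoxacin
OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O	Ciprofloxacin
CCN1CCN(c2cc3c(cc2F)c(=O)c(C(=O)O)cn3C2CC2)CC1	Enrofloxacin
CN1CCN(c2cc3c(cc2F)c(=O)c(C(=O)O)cn3-c2ccc(F)cc2)CC1	Difloxacin
CC1CN(c2cc3c(cc2F)c(=O)c(C(=O)O)cn3-c2ccc(F)cc2F)CCN1	Temafloxacin
CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23	Ofloxacin
C[C@H]1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23	Levofloxacin
CN1CCN(c2c(F)cc3c(=O)c(C(=O)O)cn4c3c2SCC4)CC1	Rufloxacin
OC(=O)c1cn(CCF)c2c(F)c(N3CCN(C)CC3)c(F)cc2c1=O	Fleroxacin
CC1CN(c2c(F)c(N)c3c(=O)c(C(=O)O)cn(C4CC4)c3c2F)CC(C)N1	Sparfloxacin
OC(=O)c1cn(-c2ccc(F)cc2F)c2nc(N3CC4C(N)C4C3)c(F)cc2c1=O	Trovafloxacin
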