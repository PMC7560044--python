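# Synthetic repository fixture: enumerated trovafloxacin derivative structures (SMILES<TAB>id)
O=C(O)c1cn(-c2ccc(F)cc2F)c2nc(N3CC4C(C3)C4[N+](=O)[O-])c(F)cc2c1=O	Derivative-1
CCC1C2CN(c3nc4c(cc3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-2
CCCC1C2CN(c3nc4c(cc3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-3
NC1C2CN(c3nc4c(c([SiH3])c3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-4
NC1C2CN(c3nc4c(c(P)c3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-5
O=C(O)c1cn(-c2ccc(F)cc2F)c2nc(N3CC4C(C3)C4[N+](=O)[O-])c(F)c([SiH3])c2c1=O	Derivative-6
COC1C2CN(c3nc4c(c([SiH3])c3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC21	Derivative-7
COC1C2CN(c3nc4c(c(P)c3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC21	Derivative-8
O=C(O)c1cn(-c2ccc(F)cc2F)c2nc(N3CC4C(S)C4C3)c(F)c(P)c2c1=O	Derivative-9
CCC1C2CN(c3nc4c(c(P)c3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-10
CCCC1C2CN(c3nc4c(c(P)c3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-11
O=C(O)c1cn(-c2ccc(F)cc2F)c2nc(N3CC4CC4C3)c(F)cc2c1=O	Derivative-12
CC1C2CN(c3nc4c(cc3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-13
C=CC1C2CN(c3nc4c(cc3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12	Derivative-14
COC1C2CN(c3nc4c(cc3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC21	Derivative-15
O=C(O)c1cn(-c2ccc(F)cc2F)c2nc(N3CC4C(S)C4C3)c(F)cc2c1=O	Derivative-16
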