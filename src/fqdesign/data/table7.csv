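residue,character,n_trovafloxacin,n_derivative_10
Leu,hydrophobic,2,1
Val,hydrophobic,2,2
Phe,hydrophobic,1,0
Met,hydrophobic,1,0
Ala,hydrophobic,2,1
Tyr,hydrophobic,1,1
Gln,hydrophilic,2,2
Arg,hydrophilic,1,2
Lys,hydrophilic,0,1
Pro,hydrophobic,0,1
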