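compound,residue,distance_A
Trovafloxacin,Gln149,5.9
Trovafloxacin,Gln156,7.6
Trovafloxacin,Arg153,8.2
Derivative-10,Gln149,6.2
Derivative-10,Gln156,9.0
Derivative-10,Arg153,12.1
Derivative-10,Arg166,17.5
Derivative-10,Lys150,6.1
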