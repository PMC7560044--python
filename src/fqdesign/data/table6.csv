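id,libdock_score,rel_change_pct
Trovafloxacin,74.7975,
Derivative-1,81.1813,8.53
Derivative-2,65.8328,-11.99
Derivative-3,67.9220,-9.19
Derivative-4,66.0899,-11.64
Derivative-5,63.7173,-14.81
Derivative-6,64.7691,-13.41
Derivative-7,66.6251,-10.93
Derivative-8,68.0351,-9.04
Derivative-9,64.7427,-13.44
Derivative-10,56.5253,-24.43
Derivative-11,61.4623,-17.83
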