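id,logkow,logkow_rel_change_pct,logt12,logt12_rel_change_pct
Trovafloxacin,2.436,,2.267,
Derivative-1,0.940,-61.41,1.801,-20.56
Derivative-2,1.537,-36.90,1.994,-12.04
Derivative-3,1.226,-49.67,1.819,-19.76
Derivative-4,1.319,-45.85,2.001,-11.73
Derivative-5,1.173,-51.85,1.988,-12.31
Derivative-6,0.991,-59.32,1.806,-20.34
Derivative-7,1.490,-38.83,2.031,-10.41
Derivative-8,1.412,-42.04,2.062,-9.04
Derivative-9,1.396,-42.69,2.006,-11.51
Derivative-10,1.166,-52.13,2.023,-10.76
Derivative-11,1.182,-51.48,2.032,-10.37
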