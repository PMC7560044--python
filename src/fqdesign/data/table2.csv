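id,structure,logfb_pred,fb_pred,logfb_rel_change_pct,ploec,ploec_rel_change_pct
Derivative-1,1-NO2-Trovafloxacin,1.738,54.702,-2.32,8.102,4.89
Derivative-2,1-C2H5-Trovafloxacin,1.738,54.702,-2.32,8.203,6.20
Derivative-3,1-C3H7-Trovafloxacin,1.724,52.966,-5.42,8.445,9.33
Derivative-4,5-SiH3-Trovafloxacin,1.722,52.723,-5.85,9.374,21.36
Derivative-5,5-PH2-Trovafloxacin,1.721,52.602,-6.07,9.166,18.67
Derivative-6,1-NO2-5-SiH3-Trovafloxacin,1.746,55.719,-0.50,8.830,14.32
Derivative-7,1-OCH3-5-SiH3-Trovafloxacin,1.735,54.325,-2.99,9.008,16.62
Derivative-8,1-OCH3-5-PH2-Trovafloxacin,1.736,54.450,-2.77,8.650,11.99
Derivative-9,1-SH-5-PH2-Trovafloxacin,1.733,54.075,-3.44,8.856,14.66
Derivative-10,1-C2H5-5-PH2-Trovafloxacin,1.628,42.462,-24.18,8.594,11.26
Derivative-11,1-C3H7-5-PH2-Trovafloxacin,1.648,44.463,-20.60,8.821,14.20
Derivative-12,1-H-Trovafloxacin,1.778,59.979,7.11,7.684,-0.52
Derivative-13,1-CH3-Trovafloxacin,1.769,58.749,4.91,8.023,3.87
Derivative-14,1-C2H3-Trovafloxacin,1.756,57.016,1.82,8.061,4.36
Derivative-15,1-OCH3-Trovafloxacin,1.772,59.156,5.64,8.012,3.73
Derivative-16,1-SH-Trovafloxacin,1.770,58.884,5.15,8.156,5.59
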