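id,min_frequency_cm1
Derivative-1,15.16
Derivative-2,13.77
Derivative-3,13.79
Derivative-4,18.05
Derivative-5,14.25
Derivative-6,18.65
Derivative-7,14.6
Derivative-8,15.14
Derivative-9,15.29
Derivative-10,9.69
Derivative-11,14.81
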