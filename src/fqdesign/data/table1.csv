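no,id,set,experimental,predicted,relative_error_pct
1,Nalidixic acid,train,1.968,1.966,-0.13
2,Oxolinic acid,train,1.886,1.893,0.35
3,Cinoxacin,train,1.833,1.830,-0.14
4,Rosoxacin,test,1.908,1.871,-1.96
5,Norfloxacin,train,1.415,1.417,0.14
6,Enoxacin,train,1.544,1.551,0.45
7,Ciprofloxacin,train,1.362,1.364,0.17
8,Enrofloxacin,train,1.544,1.526,-1.17
9,Difloxacin,train,1.531,1.536,0.30
10,Temafloxacin,train,1.447,1.438,-0.63
11,Ofloxacin,test,1.398,1.623,16.10
12,Levofloxacin,train,1.380,1.394,1.00
13,Rufloxacin,test,1.785,1.708,-4.33
14,Fleroxacin,train,1.462,1.457,-0.37
15,Sparfloxacin,train,1.362,1.362,0.02
16,Trovafloxacin,train,1.748,1.749,0.05
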