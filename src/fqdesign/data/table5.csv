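path,g_reactants_hartree,g_products_hartree,delta_g_kcal_mol
Path 1,-1704.0287,-1720.0301,-10041.0544
Path 2,-1578.1252,-1594.1148,-10033.6265
Path 3,-1617.4133,-1633.4027,-10033.5255
Path 4,-1790.2267,-1806.2479,-10053.4834
Path 5,-1841.3928,-1858.0118,-10428.5490
Path 6,-1995.2549,-2011.2238,-10020.6509
Path 7,-1905.2647,-1921.2198,-10011.9674
Path 8,-1956.4308,-1972.9852,-10388.0100
Path 9,-2240.1455,-2256.6822,-10376.9232
Path 10,-1920.5175,-1937.0769,-10391.2134
Path 11,-1959.8056,-1976.3648,-10391.0352
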