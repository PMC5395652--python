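time_min,conc_pM
2880.0,0.5977232221669403
10080.0,2.828734320338675
20160.0,4.020829371541066
30240.0,3.295821551536144
40320.0,3.097482609110801
50400.0,4.392331669920052
60480.0,5.661565610152749
70560.0,5.7870408156629685
80640.0,3.4030994294237766
90720.0,2.7128612013498166
100800.0,0.9070070533423407
110880.0,0.7715304085694075
120960.0,0.36474179626292674
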