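time_min,conc_pM
2880.0,2.1041011620916863
10080.0,5.493495466076391
20160.0,8.87734753491607
30240.0,6.100030827253907
40320.0,9.487564772713712
50400.0,12.681774863145408
60480.0,14.596716077443155
70560.0,14.090604954357476
80640.0,9.826593538835004
90720.0,5.208870484469567
100800.0,4.079975440851774
110880.0,1.7344543233494987
120960.0,0.8960040995904185
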