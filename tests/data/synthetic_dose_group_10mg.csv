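time_min,conc_pM
2880.0,4.96312143023729
10080.0,11.785196645385723
20160.0,16.029740016881536
30240.0,17.863336741372123
40320.0,18.63182707900559
50400.0,33.49619081945444
60480.0,31.95559994705157
70560.0,25.18721947817525
80640.0,20.04290821374157
90720.0,12.089374353754318
100800.0,8.279082534259382
110880.0,3.653006182486656
120960.0,1.7171140437079837
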