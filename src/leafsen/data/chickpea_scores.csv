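treatment_mM,genotype,senescent_pct,score_2day,score_3day
0,Genesis 836,0.73,1,3
0,Genesis 836,0.53,1,2
0,Genesis 836,3.30,2,4
0,Genesis 836,0.53,1,3
0,Rupali,1.64,4,4
0,Rupali,8.03,5,6
0,Rupali,1.08,2,5
0,Rupali,2.27,4,3
30,Genesis 836,1.14,2,5
30,Genesis 836,0.34,1,4
30,Genesis 836,0.91,2,3
30,Genesis 836,0.84,2,3
30,Rupali,3.69,5,5
30,Rupali,5.65,4,5
30,Rupali,11.81,7,10
30,Rupali,1.71,4,7
40,Genesis 836,0.71,2,5
40,Genesis 836,1.05,2,5
40,Genesis 836,0.91,2,3
40,Genesis 836,0.78,2,3
40,Rupali,3.13,4,5
40,Rupali,9.80,7,8
40,Rupali,11.81,4,6
40,Rupali,10.15,8,10
60,Genesis 836,0.99,4,5
60,Genesis 836,0.50,1,4
60,Genesis 836,0.81,1,4
60,Genesis 836,1.81,2,3
60,Rupali,1.40,5,5
60,Rupali,2.77,5,5
60,Rupali,2.70,5,10
60,Rupali,25.75,8,10
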