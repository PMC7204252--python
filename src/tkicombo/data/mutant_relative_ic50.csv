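mutant,imatinib,nilotinib,dasatinib,bosutinib,ponatinib,axitinib,asciminib
P223S,0.70,0.82,0.83,0.72,0.86,,24.62
G250H,0.85,1.06,0.98,0.72,0.94,,1.21
Q252H,2.78,2.41,1.44,0.98,5.56,1.92,17.96
Y253H,15.95,34.89,1.84,0.91,5.28,1.31,2.81
E255K,12.51,13.99,7.53,4.07,11.82,,3.86
E255V,10.98,27.60,3.76,2.65,11.28,1.25,1.92
K294E,0.48,0.68,0.48,0.55,0.67,,29.99
V299L,1.83,1.81,10.33,13.65,1.22,0.32,10.07
T315I,27.70,266.76,806.32,17.07,5.59,0.16,12.56
A337V,0.91,1.04,0.98,0.98,0.95,,744.64
E355G,2.56,1.37,0.71,0.63,0.77,,15.34
F359V,4.00,7.58,1.45,1.04,4.70,0.69,18.98
E459K,2.22,2.62,0.82,0.68,2.01,,4.94
P465S,1.02,0.94,0.82,0.79,0.98,,605.96
V468F,0.72,0.68,0.48,0.74,0.42,,529.32
I502L,0.62,0.76,0.70,0.67,0.78,,49.72
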