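# Steady-state oral PK constants per drug. Units: rates in 1/day, dose in mg,
# tau in days, scaled_volume (= Vd / (S F)) in m^3, c_max in ug/L, t_max and
# half_life in days. The observable columns (c_max, t_max, half_life) are the
# primary source: when present the loader refits k_a, k_e and scaled_volume
# from them, and the parameter columns serve as a consistency checkpoint.
# Axitinib and asciminib doses are estimates of a tolerable dose, not
# established treatment standards.
drug,k_a,k_e,dose,tau,scaled_volume,c_max,t_max,half_life
imatinib,20,0.868,400,1.0,0.24,2553.72,0.135528,0.798557
nilotinib,30,1.57,600,0.5,0.31,3127.08,0.082346,0.441495
dasatinib,21,5.2,200,1.0,1.3,97.8962,0.0879957,0.133298
bosutinib,10,0.717,500,1.0,2.5,335.747,0.211727,0.966732
ponatinib,11,0.768,45,1.0,0.5,144.073,0.199215,0.902535
axitinib,23,4.1,13,1.0,0.15,60.8436,0.0903596,0.16906
asciminib,27,1.6,88,1.0,0.076,1231.61,0.102375,0.433217
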