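# Absolute IC50 against native-sequence Bcr-Abl1, in ug/L (converted from
# representative Ba/F3 cell-proliferation values in uM via molecular weight).
# Used only when concentrations are taken at plasma scale; effect-normalised
# analyses depend on relative IC50 values alone.
drug,ic50_um,mw_g_per_mol,ic50_ug_per_l
imatinib,0.6,493.6,296.16
nilotinib,0.018,529.5,9.531
dasatinib,0.0008,488.0,0.3904
bosutinib,0.042,530.4,22.277
ponatinib,0.0005,532.6,0.2663
axitinib,0.25,386.5,96.625
asciminib,0.0005,449.8,0.2249
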