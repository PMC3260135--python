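sample,C_O,C_G,C_V,Cp_G_printed,Cp_V_printed,X_ext_printed
1,1.66,4.55,7.02,2.89,5.36,0.7595
2,3.16,5.20,6.03,2.04,2.87,0.8405
3,3.16,5.20,7.37,2.04,4.21,0.8543
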