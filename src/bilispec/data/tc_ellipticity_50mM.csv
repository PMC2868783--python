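# Circular dichroism (10^3 theta, 458 nm) of unconjugated bilirubin in
# 50 mM sodium taurocholate at seven pH values, with the bound-species
# fractions from the micelle partition analysis (ratios 1.41/12.9/730,
# aqueous pKa 8.12/8.44).  theta_exp readings taken at 4.6 uM total UCB
# are already multiplied by 34/4.6 to put all rows on the 34 uM basis.
# theta_calc is the published model column, retained for reference only.
pH,conc_uM,theta_exp,fs_hb,fs_b,theta_calc
7.23,34.0,-11.80,0.1661,0.5790,-13.42
7.35,4.6,-12.60,0.1474,0.6780,-11.06
8.13,4.6,0.69,0.0345,0.9550,1.50
8.15,34.0,1.90,0.0330,0.9570,1.66
9.12,4.6,5.10,0.0037,0.9946,4.75
9.35,34.0,5.38,0.00217,0.9962,4.91
11.60,34.0,5.50,0.000012,0.9986,5.13
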