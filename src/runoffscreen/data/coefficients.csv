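# Published use-exposure relationship coefficients for the USEPA California crop
# scenarios (and the Florida tomato reference), derived from 5000 stochastic
# 30-year PRZM simulations per scenario at a base application rate of 0.1 kg/ha:
# ln EI_BASE = b1 + b2*ln(AERO) + b3*ln(KOC_eff), with ln(KOC_eff) clamped at
# ln_koc_star (from below for the dissolved phase, from above for the adsorbed phase).
# Units of EI_BASE: ug/L (dissolved), ng/g-OC (adsorbed).
scenario,phase,b1,b2,b3,r_squared,ln_koc_star,base_rate
alfalfa,dissolved,5.2156,0.1907,-0.8288,0.9494,3.5,0.1
almond,dissolved,4.8131,0.1869,-0.7467,0.9335,4.5,0.1
cotton,dissolved,6.3173,0.1467,-0.7662,0.9102,5.5,0.1
sugar_beet,dissolved,4.9105,0.2412,-0.8377,0.9193,3.0,0.1
tomato,dissolved,5.9979,0.1785,-0.7844,0.8970,4.0,0.1
turf,dissolved,3.3647,0.2821,-0.8248,0.9546,0.5,0.1
wheat,dissolved,6.0764,0.1853,-0.7954,0.9487,5.0,0.1
tomato_fl,dissolved,4.9362,0.2531,-0.8063,0.9422,4.0,0.1
alfalfa,adsorbed,1.7756,0.3140,0.4936,0.6896,9.5,0.1
almond,adsorbed,0.1179,0.2116,0.6937,0.7955,10.0,0.1
cotton,adsorbed,0.9213,0.1890,0.7221,0.8466,11.0,0.1
sugar_beet,adsorbed,2.7386,0.3254,0.5118,0.6409,8.5,0.1
tomato,adsorbed,3.2070,0.1912,0.6062,0.7770,10.0,0.1
turf,adsorbed,2.7715,0.2832,0.4486,0.6106,6.5,0.1
wheat,adsorbed,1.0782,0.3233,0.5848,0.7210,10.5,0.1
tomato_fl,adsorbed,1.7065,0.4105,0.4809,0.7607,10.0,0.1
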