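# USEPA Tier-2 crop scenarios for California (plus a Florida tomato reference),
# as used to parameterize PRZM-based use-exposure relationships.
# CN = SCS curve numbers (AMC II) for fallow/cropping/residue cover; USLE factors are
# dimensionless; oc1 = organic-carbon mass fraction of the surface soil layer.
# bulk_density (g/cm3) and water_content (volumetric) are surrogate-simulator defaults,
# not scenario-file transcriptions. app_window and irrigated encode the represented use
# pattern (dormant, pre-emergent or in-season application; gravity irrigation).
name,use_pattern,soil,hydro_group,weather_station,cn_fallow,cn_cropping,cn_residue,usle_k,usle_ls,usle_p,usle_c_min,usle_c_max,oc1,bulk_density,water_content,app_window_start,app_window_end,irrigated
alfalfa,"Pasture, gravity irrigation",Sacramento clay,D,Fresno,90,88,89,0.20,0.30,1.0,0.051,0.217,0.0177,1.35,0.30,06-01,06-30,1
almond,"Dormant application",Manteca fine sandy loam,C,Sacramento,84,79,84,0.28,0.30,1.0,0.034,0.221,0.0081,1.35,0.30,01-01,01-30,0
cotton,"Field crop, gravity irrigation",Twisselman clay,C,Fresno,89,86,89,0.21,0.37,1.0,0.054,0.412,0.0029,1.35,0.30,06-01,06-30,1
sugar_beet,"Field crop, gravity irrigation",Ryde clay loam,C,Fresno,89,86,89,0.28,0.30,1.0,0.015,0.769,0.0348,1.35,0.30,06-01,06-30,1
tomato,"Tomato, gravity irrigation",Stockton clay,D,Fresno,91,87,91,0.24,0.13,1.0,0.035,0.255,0.0095,1.35,0.30,06-01,06-30,1
turf,"Pre-emergent application",Capay silty clay loam,D,San Francisco,80,80,80,0.37,1.80,0.5,0.001,0.001,0.356,1.35,0.30,02-01,03-02,0
wheat,"Grain, gravity irrigation",San Joaquin loam,D,Fresno,92,89,90,0.37,0.79,1.0,0.027,0.604,0.0044,1.35,0.30,06-01,06-30,1
tomato_fl,"Tomato scenario in Florida",Riviera sand,C,West Palm Beach,91,87,91,0.03,0.20,1.0,0.177,0.938,0.0116,1.35,0.30,06-01,06-30,0
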