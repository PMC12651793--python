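food_id,name,carbohydrate,protein,fat,fiber,human_gi,egi_goni,egi_new
lotus_root_powder,Lotus root powder (pure),93.0,0.2,0.0,0.1,39,46,36
grain_millet,Grain millet,73.5,9.0,3.1,1.6,71,78,69
rice,Rice,71.8,12.7,0.9,0.6,82,86,75
chinese_yam,Chinese yam,69.4,9.1,1.0,1.4,51,56,45
lotus_seed_powder,Lotus seed powder,64.2,17.2,2,3.0,51,56,41
dumpling_wrapper,Dumpling wrapper,57.0,9.3,1.4,2.2,70,83,68
biscuits,Biscuits,55.0,12.0,10.0,10.0,52,49,38
milk_powder,Milk powder,51.7,20.1,21.2,0.0,40,42,40
dumplings,Dumplings,26.6,8.8,12.3,3.2,50,72,55
black_soybean,Black soybean,23.4,36,15.9,10.2,42,51,27
potato,Potato,16.5,2,0.2,0.7,65,74,63
apple,Apple,12.3,0.2,0.2,1.2,36,64,39
pear,Pear,10.2,0.4,0.2,3.1,36,51,30
milk,Milk (pure),3.4,3,3.2,0,27,52,28
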