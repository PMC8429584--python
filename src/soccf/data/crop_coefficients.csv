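crop_name,slope,intercept,root_shoot_ratio,c_fraction,base_yield
wheat,1.3,0.5,0.23,0.45,3.5
maize,1.0,0.6,0.22,0.45,5.5
rice,1.4,0.5,0.16,0.45,4.5
barley,1.2,0.5,0.22,0.45,3.0
oats,1.3,0.5,0.25,0.45,2.8
rye,1.4,0.5,0.22,0.45,2.5
soybean,0.9,0.3,0.19,0.45,2.5
sunflower,1.1,0.3,0.22,0.45,2.2
rapeseed,1.0,0.3,0.19,0.45,2.8
potato,0.3,0.3,0.2,0.42,8.0
sweet_potato,0.3,0.3,0.2,0.42,6.0
sugarcane,0.2,0.5,0.18,0.45,25.0
sugar_beet,0.25,0.3,0.2,0.42,12.0
tomato,0.3,0.3,0.2,0.42,5.0
cabbage,0.3,0.3,0.2,0.42,6.0
onion,0.25,0.3,0.2,0.42,5.0
cotton,1.2,0.3,0.17,0.45,2.2
groundnut,1.0,0.3,0.2,0.45,2.0
olive,0.4,1.0,0.3,0.48,2.0
grape,0.4,1.0,0.3,0.48,3.0
citrus,0.4,1.0,0.3,0.48,4.0
apple,0.4,1.0,0.3,0.48,4.5
coffee,0.4,1.0,0.3,0.48,1.5
cassava,0.4,0.3,0.2,0.42,7.0
yam,0.4,0.3,0.2,0.42,5.0
lentil,1.1,0.3,0.22,0.45,1.2
chickpea,1.1,0.3,0.22,0.45,1.3
bean,1.1,0.3,0.22,0.45,1.5
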