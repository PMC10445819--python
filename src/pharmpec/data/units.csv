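symbol,category,multiplier,note
g,mass,1,
mg,mass,0.001,
ug,mass,1e-06,micrograms; mcg and the micro sign normalise to ug
ng,mass,1e-09,
kg,mass,1000,
g/l,per_volume,1,
mg/l,per_volume,0.001,
ug/l,per_volume,1e-06,
g/ml,per_volume,1000,
mg/ml,per_volume,1,
ug/ml,per_volume,0.001,
mg/100ml,per_volume,0.01,
g/100ml,per_volume,10,
g/g,per_mass,1,
mg/g,per_mass,0.001,
ug/g,per_mass,1e-06,
g/kg,per_mass,0.001,
mg/kg,per_mass,1e-06,
%w/v,percent_wv,10,percent weight per volume; 1% = 10 g/L
%w/w,percent_ww,0.01,percent weight per weight; 1% = 0.01 g/g
%,percent,,interpretation depends on the product medium
iu,non_mass,,international units
ie,non_mass,,international units (Norwegian IE)
iu/ml,non_mass,,
ie/ml,non_mass,,
mill iu,non_mass,,
e,non_mass,,enzyme units
pill,package_count,1,
pills,package_count,1,
tablet,package_count,1,
tablets,package_count,1,
capsule,package_count,1,
capsules,package_count,1,
dose,package_count,1,
doses,package_count,1,
item,package_count,1,
items,package_count,1,
stk,package_count,1,Norwegian count unit
piece,package_count,1,
pieces,package_count,1,
suppository,package_count,1,
suppositories,package_count,1,
patch,package_count,1,
patches,package_count,1,
ml,package_volume,0.001,
cl,package_volume,0.01,
dl,package_volume,0.1,
l,package_volume,1,
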