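food_id,category,omega,phi,land_type,area_per_kg_override,second_land_type,second_area_per_kg
cereals,crop,1.59,,arable,,,
roots_tubers,crop,2.08,,arable,,,
legumes,crop,5.07,,arable,,,
oil_crops,crop,12.58,,arable,,,
vegetables,crop,0.28,,arable,,,
sugar,crop,1.03,,arable,,,
pork,animal,1.94,0.25,arable,7.92,,
beef_mutton,animal,2.63,0.32,arable,8.35,,
poultry,animal,2.29,0.35,arable,,,
eggs,animal,2.29,0.60,arable,,,
dairy,animal,2.63,1.82,arable,,,
aquatic,aquatic,2.46,2.22,waters,1.23,arable,
fruit_fresh,fruit_fresh,0.43,,horticultural,,,
fruit_dried,fruit_dried,1.72,,horticultural,,,
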