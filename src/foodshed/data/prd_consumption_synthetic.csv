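food_id,kg_per_capita_year
cereals,130.0
roots_tubers,10.0
legumes,8.0
oil_crops,10.0
vegetables,105.0
pork,30.0
beef_mutton,7.0
poultry,15.0
aquatic,34.4
eggs,11.0
dairy,13.0
sugar,1.5
fruits,45.6
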