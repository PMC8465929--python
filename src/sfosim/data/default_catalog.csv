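food_id,name,group,shelf_life_weeks,c_store,ease_of_delivery,mean_price
apple,Apples,fruits,2,0.35,4,0.75
banana,Bananas,fruits,1,0.16,4,0.35
orange,Oranges,fruits,2,0.40,3,0.90
grapes,Grapes,fruits,1,1.15,3,2.50
tomato,Tomatoes,vegetables,1,0.45,3,1.00
lettuce,Lettuce,vegetables,1,0.80,2,1.80
carrot,Carrots,vegetables,3,0.55,4,1.20
onion,Onions,vegetables,4,0.36,4,0.80
potato,Potatoes,vegetables,6,0.32,4,0.70
broccoli,Broccoli,vegetables,1,0.72,2,1.60
milk,Low-fat milk,dairy,2,1.25,4,2.80
yogurt,Yogurt,dairy,3,0.50,3,1.10
cheese,Cheese,dairy,4,1.60,3,3.50
eggs,Eggs,protein,4,1.15,4,2.60
tuna,Canned tuna,protein,52,0.68,5,1.50
beans,Dried beans,protein,52,0.80,5,1.80
peanut_butter,Peanut butter,protein,26,1.35,5,3.00
bread,Whole-wheat bread,grains,1,1.10,4,2.40
rice,Brown rice,grains,52,1.00,5,2.20
oats,Oatmeal,grains,52,1.25,5,2.80
cereal,Whole-grain cereal,grains,26,1.60,4,3.60
tortilla,Corn tortillas,grains,4,1.15,4,2.50
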