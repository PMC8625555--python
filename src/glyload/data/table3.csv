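meal_id,name,kcal,carb_g,fiber_g,sugars_g,protein_g,fat_g,tier_g,ref_iauc_mean,ref_iauc_sd,meal_iauc_mean,meal_iauc_sd,significance,gi_mean,gi_sd,gl_mean,gl_sd,gi_sd_anomaly
1,Corn dog,210,26,2,7,5,10,25,2754,762,1424,401,***,53,14,13,3,0
2,Roasted mixed grain powder,125,23,5.5,3,8,1.3,25,2747,1320,1372,491,***,54,18,9,3,0
3,Chocolate cereal bar with nuts,246,25,4,14,8,14,25,2744,442,1936,272,**,72,14,15,3,0
4,Sweet potato salad,210,25,1,15,1,12,25,2877,251,1574,542,**,55,18,13,4,0
5,Pork and burdock root fried rice,175,26,2,3,11,3,25,3376,160,1990,129,,60,24,15,6,0
6,Strawberry smoothie,100,25,2,22,1,0,25,2898,972,2049,684,*,67,13,15,3,0
7,Crispy tofu in garlic teriyaki sauce,230,26,6,10,18,7,25,3077,858,499,194,***,18,70,4,1,1
8,Sweet pumpkin and chestnut soup,180,25,0,15,4,7,25,3533,791,1328,399,**,37,6,9,1,0
9,Lentils and rice with braised tofu,340,50,5,6,19,8,50,4139,115,2583,142,**,61,21,27,9,0
10,Spaghetti with tomato meat sauce and cheese,305,50,2,8,11,7,50,4075,122,2044,117,***,49,19,24,9,0
11,"Black beans and barley rice, spicy braised chicken, bean sprouts, cucumber and balloon flower root salad",363,50,7.1,10,23,7.9,50,4091,1025,2481,883,**,62,19,27,8,0
12,Semi-dried slices of sweet potato,195,49,5,10,2,0,50,4200,110,2298,110,**,57,23,25,1,0
13,Meat dumplings (10 pieces),493,52,7,2,22,24,50,4144,1121,1515,494,***,40,20,18,9,0
14,Korean thistle and barley rice,296,50,1,1,6,8,50,4472,983,2631,910,**,59,15,29,7,0
15,Corn dogs (2 pieces),420,52,4,14,10,20,50,4144,1121,2818,932,**,68,12,33,6,0
16,Multigrain cereal,240,50,2,18,4,3,50,4404,915,2959,764,*,70,20,33,1,0
17,Three bean salad (chickpea pea and lentil) and quinoa with black sesame dressing,422,46,16,12,14,20,50,3972,136,576,169,**,18,50,5,1,1
18,"Korean barbecued beef and mushroom with rice, tomato chili sauce, veggie sticks, braised burdock root",305,54,7.1,16,14,3.9,50,4394,1302,2539,1801,,59,19,29,9,0
19,"Chicken breast fried rice with bean sprouts, salad, kimchi, quail egg soy sauce",392,53,6.1,9,19,11.5,50,3966,1256,2486,400,,65,13,31,6,0
20,"Guinea corn and rice, stir-fried octopus, veggie sticks, white kimchi, stir-fried anchovies",295,52,6.7,11,14,3.2,50,3966,1256,2852,539,*,69,11,31,5,0
21,"Brown rice, beef stroganoff, grilled vegetables, coleslaw",320,53,6.4,15,17,4.4,50,4381,1307,2016,632,*,57,5,27,2,0
22,Beef and mushroom mixed rice,345,55,4,6,8,11,50,5373,788,3926,694,,74,15,38,8,0
23,Stir-fried rice with seafood and vegetables,315,54,4,4,11,7,50,5286,961,3119,494,*,65,9,32,4,0
24,"Steamed lotus root rice mixed with sweet pumpkin, mushroom, lentils",335,58,2,5,7,9,50,5286,961,2979,1257,*,58,22,32,13,0
25,"Oat rice, fish cutlet with broccoli cream sauce, stir-fried bamboo shoots and mushroom, pickled radish, stir-fried anchovies with peanuts, bean salad",411,71,7,N/A,16,7,75,6012,147,4619,149,,76,80,49,5,1
26,"Brown rice, Korean barbecued duck, seasoned sweet potato stalks, dried slices of daikon, stir-fried anchovies with nuts, bean salad",476,74,7,14,18,12,75,4585,737,2566,536,**,56,10,38,7,0
27,Multigrain rice with quinoa,420,74,2,8,9,10,75,5326,159,3842,992,*,73,12,53,8,0
28,"Semi-dried slices of sweet potato, corn dog",405,75,7,17,7,10,75,5326,159,2847,116,**,57,25,39,2,0
29,"Brown rice, tofu and grilled short rib patties, white kimchi, seasoned aster, green leafy vegetables with mustard dressing",581,73,11,13,22,22,75,4646,796,2180,688,**,47,12,29,7,0
30,Korean black bean sauce noodles,660,99,3,13,23,20,75,5292,1302,2777,445,*,57,18,54,17,0
31,Brown rice with seasoned aster,385,68,1,1,8,9,75,5602,1309,3487,939,,65,17,44,11,0
32,Cold buckwheat noodles with spicy sauce,495,103,0,18,12,4,75,5602,1309,2621,713,**,47,8,48,8,0
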