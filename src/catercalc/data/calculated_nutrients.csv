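category,dish_name,method,fat,protein,sodium,carbohydrate
Rice,Rice,Boiling,0.62,3.41,0.0005,37.47
Rice,Steamed rice,Steaming,0.76,3.23,0.0046,35.48
Rice,Fried rice,Stir-frying,10.05,6.98,0.2295,68.91
Noodles,Soup noodles,Boiling,0.06,4.39,0.0210,34.33
Noodles,Fried noodles,Stir-frying,15.24,20.27,0.2261,32.26
Chicken breast,Braised chicken breast,Stewing (with soy sauce),4.77,22.94,0.3808,1.01
Chicken breast,Deep-fried chicken breast (breaded with flour),Deep-frying,46.52,24.99,0.5104,1.30
Chicken breast,Fried Chicken,Stir-frying,28.63,20.73,0.4245,1.08
Chicken Legs,Braised Chicken Legs,Stewing (with soy sauce),5.98,12.28,0.2069,0.02
Chicken Legs,Steamed chicken thighs (cut into pieces and steamed),Steaming,6.46,18.52,0.1040,0.03
Chicken Legs,Fried chicken thighs (coated with flour),Deep-frying,18.83,18.59,0.4129,1.30
Chicken Legs,Grilled Chicken Legs,Roasting,11.17,26.23,0.9632,4.58
Pork belly,Braised Pork,Stewing (with soy sauce),30.76,14.40,0.3509,1.14
Pork belly,Steamed pork practice,Steaming,28.88,15.12,0.2579,0.47
Pork belly,Stir-fried Shredded Pork with Green Pepper,Stir-frying,27.02,12.08,0.1010,3.47
Pork belly,Grilled Pork,Roasting,30.68,13.88,0.0930,2.85
Pork Legs,Steamed pork with vermicelli,Steaming,16.23,12.05,0.1672,4.31
Pork Legs,Small crispy pork (coated with flour and fried),Deep-frying,45.09,28.47,0.6683,10.05
Pork Legs,Pasteurized pork,Stir-frying,23.20,34.17,0.3828,8.28
Pork Legs,Braised Pork,Stewing (with soy sauce),26.24,15.01,0.1059,6.87
Brisket,Braised Beef Brisket,Stewing (with soy sauce),23.85,11.16,0.1261,1.09
Brisket,Grilled Beef Brisket,Roasting,31.22,17.27,0.1196,2.01
Brisket,Stir Fried Beef Brisket,Stir-frying,36.19,17.64,0.2580,0.67
Beef Tendon,Stir Fried Beef,Stir-frying,10.19,21.05,0.1859,0.39
Beef Tendon,Grilled Beef Tendon with Sauce,Roasting,17.82,60.10,0.3190,7.70
Beef Tendon,Braised Beef Tendon,Stewing (with soy sauce),8.10,15.74,0.4907,2.04
Leg of lamb,(Cumin) Lamb,Stir-frying,11.11,16.91,0.2043,0.65
Leg of lamb,Roast Lamb,Roasting,10.75,16.94,0.1787,0.56
Leg of lamb,Braised Lamb Shank,Stewing (with soy sauce),12.46,24.37,0.1977,0.27
Grass carp,Braised Grass Carp,Stewing (with soy sauce),9.58,4.72,0.1969,2.06
Grass carp,Fried Grass Carp,Deep-frying,9.60,7.49,0.1985,6.08
Grass carp,Steamed Grass Carp,Steaming,4.35,14.33,0.6949,0.42
Grass carp,Grilled Grass Carp,Roasting,34.22,45.66,1.0224,0.15
Hairtail,Steamed hairtail,Steaming,8.94,38.96,1.8415,7.68
Hairtail,Braised hairtail,Stewing (with soy sauce),8.04,5.35,0.1396,1.51
Hairtail,Deep Fried hairtail Pieces,Deep-frying,8.53,9.92,0.2946,6.46
Shrimp,Prawns in oil,Deep-frying,14.65,15.84,0.4560,14.03
Shrimp,Steamed shrimp,Steaming,2.71,39.10,0.8164,2.66
Shrimp,Boiled Shrimp,Quick-boiling,2.21,42.11,0.7947,2.63
Eggs,Scrambled eggs with green peppers,Stir-frying,11.07,6.71,0.4120,5.84
Eggs,Hard-boiled eggs,Stewing (with soy sauce),6.52,15.22,0.1891,5.43
Eggs,Fried Eggs,Stir-frying,32.66,9.70,0.0767,0.81
Pakchoi cabbage,Stir Fried Pakchoi cabbage,Stir-frying,8.76,1.10,0.8042,2.21
Pakchoi cabbage,Quick-boiled Pakchoi cabbage,Quick-boiling,0.00,1.23,0.1210,2.47
Potatoes,Hot and Sour Shredded Potatoes,Stir-frying,29.70,5.63,1.2167,47.70
Potatoes,Baked Potatoes,Roasting,3.21,1.74,0.0043,14.78
Potatoes,French fries (chips),Deep-frying,16.50,1.45,0.0041,12.32
Potatoes,Boiled potatoes,Stewing (with soy sauce),4.20,0.76,0.0361,5.97
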