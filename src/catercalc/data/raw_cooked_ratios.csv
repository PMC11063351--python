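category,dish_name,method,ratio
Rice,Steamed Rice,Steaming,0.49
Rice,Fried Rice,Stir-frying,0.48
Noodles,Noodles in Soup,Boiling,0.84
Noodles,Fried Noodles,Stir-frying,0.78
Chicken breast,Braised Chicken Breast,Stewing (with soy sauce),1.05
Chicken breast,Deep-fried chicken breast (covered with flour),Deep-frying,1.25
Chicken breast,Fried Chicken,Stir-frying,0.97
Chicken Legs,Braised Chicken Thighs,Stewing (with soy sauce),1.22
Chicken Legs,Steamed chicken thighs (cut into pieces and steamed),Steaming,0.95
Chicken Legs,Fried Chicken Legs (Flour Coated),Deep-frying,1.08
Chicken Legs,Grilled chicken thighs,Roasting,1.43
Pork Five-flower,Braised Pork,Stewing (with soy sauce),1.28
Pork Five-flower,Stir-fried Shredded Pork with Green Pepper,Stir-frying,1.05
Pork shank,Steamed Pork in Vermicelli,Steaming,0.65
Pork shank,Small crispy pork (breaded and fried),Deep-frying,1.25
Pork shank,Back-pot meat,Stir-frying,1.12
Pork shank,Braised Pork,Stewing (with soy sauce),1.26
Beef Brisket,Braised Beef Brisket,Stewing (with soy sauce),1.35
Beef Brisket,Roast Beef Brisket,Roasting,1.07
Beef Brisket,Stir Fried Beef Brisket,Stir-frying,1.16
Beef Tendon,Stir Fried Beef,Stir-frying,1.06
Beef Tendon,Roast Beef Tendon with Sauce,Roasting,1.10
Beef Tendon,Braised Beef Tendon,Stewing (with soy sauce),1.34
Leg of lamb,(Cumin) Lamb,Stir-frying,1.21
Leg of lamb,Roast Lamb,Roasting,1.24
Leg of lamb,Braised Lamb Shank,Stewing (with soy sauce),1.47
Grass carp,Braised Grass Carp,Stewing (with soy sauce),0.96
Grass carp,Deep Fried Grass Carp,Deep-frying,1.11
Grass carp,Steamed Grass Carp,Steaming,1.01
Grass carp,Grilled Grass Carp,Roasting,1.11
Hairtail,Steamed hairtail,Steaming,1.09
Hairtail,Braised hairtail,Stewing (with soy sauce),0.91
Hairtail,Deep Fried hairtail Pieces,Deep-frying,1.17
Shrimp,Stewed Prawns,Deep-frying,0.82
Shrimp,Steamed Prawns,Steaming,1.27
Shrimp,Boiled Prawns,Stewing (with soy sauce),1.13
Egg,Scrambled Eggs with Green Peppers,Stir-frying,0.92
Egg,Boiled Eggs,Stewing (with soy sauce),1.01
Egg,Fried Eggs,Stir-frying,1.14
Pakchoi cabbage,Stir Fried pakchoi cabbage,Stir-frying,1.05
Pakchoi cabbage,Quick-boiledpPakchoi cabbage,Quick-boiling,1.00
Potatoes,Spicy and sour shredded potatoes,Stir-frying,1.12
Potatoes,Fried French fries (slices),Deep-frying,1.53
Potatoes,Boiled potatoes,Stewing (with soy sauce),1.05
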