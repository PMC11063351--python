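category,dish_name,method,fat,fat_star,protein,protein_star,sodium,sodium_star,carbohydrate,carbohydrate_star
Rice,Rice,Boiling,0.55,False,1.08,False,0.36,True,0.63,False
Rice,Steamed rice,Steaming,0.62,False,0.86,False,0.90,False,0.66,False
Rice,Fried rice,Stir-frying,1.68,False,2.17,True,0.47,True,1.44,False
Noodles,Soup noodles,Boiling,0.04,True,0.95,False,7.24,True,0.77,False
Noodles,Fried noodles,Stir-frying,3.50,True,3.24,True,0.47,True,0.60,False
Chicken breast,Braised chicken breast,Stewing (with soy sauce),0.93,False,0.92,False,1.39,False,0.07,True
Chicken breast,Deep-fried chicken breast (breaded with flour),Deep frying,4.95,True,0.84,False,2.24,True,0.09,True
Chicken breast,Fried Chicken,Stir-frying,4.06,True,0.97,False,2.24,True,0.07,True
Chicken Legs,Braised Chicken Legs,Stewing (with soy sauce),0.67,False,0.58,False,0.49,True,0.00,True
Chicken Legs,Steamed chicken thighs (cut into pieces and steamed),Steaming,0.79,False,0.86,False,0.40,True,0.00,True
Chicken Legs,Fried chicken thighs (coated with flour),Deep frying,1.48,False,0.83,False,1.12,False,0.09,True
Chicken Legs,Grilled Chicken Legs,Roasting,1.15,False,1.07,False,1.19,False,0.33,True
Pork belly,Braised Pork,Stewing (with soy sauce),0.76,False,0.76,False,1.11,False,0.11,True
Pork belly,Steamed pork practice,Steaming,1.17,False,0.82,False,1.03,False,0.03,True
Pork belly,Stir-fried Shredded Pork with Green Pepper,Stir-frying,0.86,False,0.65,False,0.23,True,0.31,True
Pork belly,Grilled Pork,Roasting,0.85,False,0.75,False,0.39,True,0.25,True
Pork Legs,Steamed pork with vermicelli,Steaming,1.21,False,0.85,False,0.21,True,0.16,True
Pork Legs,Small crispy pork (coated with flour and fried),Deep frying,2.85,True,1.10,False,1.06,False,0.57,False
Pork Legs,Pasteurized pork,Stir-frying,0.68,False,2.03,True,0.69,False,1.06,False
Pork Legs,Braised Pork,Stewing (with soy sauce),0.88,False,0.69,False,0.22,True,0.58,False
Brisket,Braised Beef Brisket,Stewing (with soy sauce),0.99,False,0.49,True,0.18,True,0.09,True
Brisket,Grilled Beef Brisket,Roasting,1.94,False,0.94,False,0.34,True,0.10,True
Brisket,Stir Fried Beef Brisket,Stir-frying,1.44,False,1.01,False,0.32,True,0.06,True
Beef Tendon,Stir Fried Beef,Stir-frying,0.86,False,0.94,False,0.20,True,0.04,True
Beef Tendon,Grilled Beef Tendon with Sauce,Roasting,2.58,True,2.61,True,0.73,False,0.45,True
Beef Tendon,Braised Beef Tendon,Stewing (with soy sauce),0.48,True,0.62,False,0.72,False,0.15,True
Leg of lamb,(Cumin) Lamb,Stir-frying,0.45,True,0.76,False,0.30,True,0.07,True
Leg of lamb,Roast Lamb,Roasting,0.58,False,0.67,False,0.34,True,0.06,True
Leg of lamb,Braised Lamb Shank,Stewing (with soy sauce),0.64,False,0.86,False,0.34,True,0.06,True
Grass carp,Braised Grass Carp,Stewing (with soy sauce),0.64,False,0.30,True,0.25,True,0.13,True
Grass carp,Fried Grass Carp,Deep frying,1.14,False,0.35,True,0.48,True,0.32,True
Grass carp,Steamed Grass Carp,Steaming,1.13,False,0.70,False,1.04,False,0.03,True
Grass carp,Grilled Grass Carp,Roasting,4.03,True,1.84,False,1.79,False,0.01,True
Hairtail,Steamed hairtail,Steaming,2.18,True,1.78,False,3.02,True,0.52,False
Hairtail,Braised hairtail,Stewing (with soy sauce),0.94,False,0.27,True,0.19,True,0.10,True
Hairtail,Deep Fried hairtail Pieces,Deep frying,0.59,False,0.42,True,0.45,True,0.51,False
Shrimp,Prawns in oil,deep frying,1.59,False,0.75,False,0.94,False,0.60,False
Shrimp,Steamed shrimp,Steaming,0.90,False,1.68,False,1.03,False,0.21,True
Shrimp,Boiled Shrimp,Quick-boiling,0.94,False,2.00,True,4.46,True,0.19,True
Eggs,Scrambled eggs with green peppers,Stir-frying,0.44,True,0.60,False,0.50,True,0.67,False
Eggs,Hard-boiled eggs,Stewing (with soy sauce),0.58,False,1.06,False,1.17,False,0.39,True
Eggs,Fried Eggs,Stir-frying,1.33,False,0.70,False,0.43,True,0.07,True
Pakchoi cabbage,Stir Fried Pakchoi cabbage,Stir-frying,1.23,False,0.56,False,0.92,False,0.12,True
Pakchoi cabbage,Quick-boiled Pakchoi cabbage,Quick-boiling,0.00,True,0.81,False,1.50,False,0.11,True
Potatoes,Hot and Sour Shredded Potatoes,Stir-frying,2.97,True,4.58,True,1.98,False,1.87,False
Potatoes,Baked Potatoes,Roasting,0.13,True,0.66,False,0.57,False,0.51,False
Potatoes,French fries (chips),Deep frying,2.24,True,0.53,False,0.29,True,0.37,True
Potatoes,Boiled potatoes,Stewing (with soy sauce),1.11,False,0.36,True,0.07,True,0.21,True
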