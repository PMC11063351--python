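category,group,subclass,n_samples,processing_methods,corresponding_dishes
Grain,,Rice,9,"Steaming, boiling, stir-frying","Steamed rice, boiled rice, stir-fried rice"
Grain,,Noodles,9,"Boiling, stir-frying","Noodles in soup, lao mein, chow mein"
Meat,Chicken,Chicken breast,9,"Stewing (with soy sauce), deep-frying, stir-frying","Braised chicken breast, fried chicken breast (covered with flour), fried chicken"
Meat,Chicken,Chicken leg,12,"Stewing, deep-frying, steaming, roasting","Braised chicken thighs, steamed chicken thighs (cut into pieces and steamed), fried chicken thighs (covered with flour), baked chicken thighs"
Meat,Pork,pork belly,12,"Steaming, Stewing (with soy sauce), stir-frying, roasting","Braised Pork, Button Pork, Shredded Pork with Green Pepper, Roasted Pork"
Meat,Pork,Pork legs,12,"Steaming, Stewing (with soy sauce), stir-frying, deep-frying","Steamed pork with vermicelli, braised pork, roasted pork, crispy pork"
Beef and mutton,,Brisket,9,"Stewing (with soy sauce), stir-frying, roasting","Braised beef brisket, roast beef brisket, stir-fried beef brisket"
Beef and mutton,,Beef tendon,9,"Stewing (with soy sauce), stir-frying, roasting","Stir-fried beef, roast beef tendon with sauce, braised beef tendon"
Beef and mutton,,Leg of lamb,9,"Stewing (with soy sauce), stir-frying, roasting","(Cumin) lamb, roast lamb, braised lamb leg"
Fish and shrimp,,Grass carp,12,"Steaming, Stewing (with soy sauce), stir-frying, roasting","Braised grass carp, fried grass carp, steamed grass carp, grilled grass carp"
Fish and shrimp,,Scallops,9,"Steaming, Stewing (with soy sauce), deep-frying","Steamed scallops, braised scallops, fried scallop pieces"
Fish and shrimp,,Shrimp,9,"Steaming, Stewing (with soy sauce), deep-frying","Prawns in oil, steamed prawns, boiled prawns"
Egg,,Eggs,9,"Stewing (with soy sauce), stir-frying","Scrambled eggs with green peppers, boiled eggs, fried eggs"
Vegetables,,Leafy vegetables,6,"Quick-boiling, stir-frying",Vegetable stir-fry with stir-fried greens and boiled greens
Vegetables,,Rootstock (potato),9,"Stewing (with soy sauce), stir-frying, roasting, deep-frying","Hot and sour shredded potatoes, roasted potatoes, french fries (slices), boiled potatoes"
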