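category,dish_name,method,fat_mean,fat_sd,protein_mean,protein_sd,sodium_mean,sodium_sd,carbohydrate_mean,carbohydrate_sd
Rice,Rice,Boiling,1.12,0.59,3.16,0.15,0.0014,0.0004,59.73,14.33
Rice,Steamed rice,Steaming,1.22,0.11,3.77,0.28,0.0051,0.0007,53.39,2.45
Rice,Fried rice,Stir-frying,5.97,2.85,3.21,0.44,0.487,0.0954,47.8,6.89
Noodles,Soup noodles,Boiling,1.53,1.31,4.61,0.46,0.0029,0.0002,44.74,1.89
Noodles,Fried noodles,Stir-frying,4.35,1.38,6.25,0.26,0.4837,0.0205,53.69,1.54
Chicken breast,Braised chicken breast,Stewing (with soy sauce),5.14,1.58,24.91,0.21,0.273,0.053,13.9,2.07
Chicken breast,Deep-fried chicken breast (breaded with flour),Deep-frying,9.4,2.14,29.66,3.23,0.2277,0.0612,13.84,2.47
Chicken breast,Fried Chicken,Stir-frying,7.05,2.16,21.43,3.76,0.1893,0.025,16.4,4.22
Chicken Legs,Braised Chicken Legs,Stewing (with soy sauce),8.87,2.7,21.21,2.14,0.425,0.0965,14.83,1.64
Chicken Legs,Steamed chicken thighs (cut into pieces and steamed),Steaming,8.13,1.6,21.47,1.34,0.2617,0.01,12.45,0.81
Chicken Legs,Fried chicken thighs (coated with flour),Deep-frying,12.74,0.6,22.27,0.85,0.3687,0.0438,14.84,2.65
Chicken Legs,Grilled Chicken Legs,Roasting,9.7,1.42,24.61,0.44,0.8093,0.1361,13.86,1.36
Pork belly,Braised Pork,Stewing (with soy sauce),40.27,9.79,19.03,1.11,0.3167,0.0898,10.36,5.32
Pork belly,Steamed pork practice,Steaming,24.6,14.32,18.4,3.63,0.251,0.1191,14.47,3.41
Pork belly,Stir-fried Shredded Pork with Green Pepper,Stir-frying,31.24,9.89,18.62,3.32,0.4323,0.0498,11.1,1.68
Pork belly,Grilled Pork,Roasting,35.98,12.02,18.55,4.12,0.24,0.0148,11.47,1.13
Pork Legs,Steamed pork with vermicelli,Steaming,13.42,6.66,14.23,2.79,0.7963,0.042,27.72,2.44
Pork Legs,Small crispy pork (coated with flour and fried),Deep-frying,15.83,1.68,25.92,4.35,0.6317,0.2183,17.56,3.46
Pork Legs,Pasteurized pork,Stir-frying,34.1,21.23,16.83,4.67,0.5587,0.1042,7.85,8.73
Pork Legs,Braised Pork,Stewing (with soy sauce),29.88,12.04,21.77,4.91,0.4813,0.099,11.84,0.93
Brisket,Braised Beef Brisket,Stewing (with soy sauce),24,2.49,22.78,1.5,0.686,0.2842,12.54,2.7
Brisket,Grilled Beef Brisket,Roasting,16.11,11.87,18.28,4.82,0.349,0.1615,19.78,13.52
Brisket,Stir Fried Beef Brisket,Stir-frying,25.2,11.52,17.5,3.71,0.794,0.1455,11.07,2.85
Beef Tendon,Stir Fried Beef,Stir-frying,11.87,4.65,22.39,1.86,0.9497,0.2829,9.88,4.4
Beef Tendon,Grilled Beef Tendon with Sauce,Roasting,6.9,1.38,23.07,1.45,0.4377,0.0941,16.93,0.28
Beef Tendon,Braised Beef Tendon,Stewing (with soy sauce),17.02,7.6,25.4,1.6,0.6823,0.1627,13.63,3.95
Leg of lamb,(Cumin) Lamb,Stir-frying,24.47,11.5,22.17,3.71,0.6925,0.1138,8.79,2.09
Leg of lamb,Roast Lamb,Roasting,18.38,1.42,25.27,3.08,0.524,0.0226,9.14,1.74
Leg of lamb,Braised Lamb Shank,Stewing (with soy sauce),19.57,0.21,28.48,1.91,0.577,0.1117,4.63,0.73
Grass carp,Braised Grass Carp,Stewing (with soy sauce),15,3.73,15.59,0.79,0.7773,0.0917,16.38,2.24
Grass carp,Fried Grass Carp,Deep-frying,8.39,4.33,21.53,0.54,0.41,0.0806,19.27,1.73
Grass carp,Steamed Grass Carp,Steaming,3.85,0.94,20.33,2.28,0.6653,0.1049,16.56,2.57
Grass carp,Grilled Grass Carp,Roasting,8.5,3.45,24.87,1.97,0.571,0.0676,11.68,0.6
Scallops,Steamed Scallop,Steaming,4.1,0.25,21.87,1.56,0.6107,0.0408,14.76,2.11
Scallops,Braised Scallops,Stewing (with soy sauce),8.55,1.55,19.49,1.07,0.7253,0.0804,15.89,2.58
Scallops,Deep Fried Scallop Pieces,Deep-frying,14.54,4.87,23.74,0.9,0.6553,0.1562,12.69,2.4
Shrimp,Prawns in oil,Deep-frying,9.24,1.88,21.03,1.45,0.483,0.0759,23.56,2.19
Shrimp,Steamed shrimp,Steaming,3.02,1.05,23.29,3.08,0.7947,0.1456,12.91,1.49
Shrimp,Boiled Shrimp,Stewing (with soy sauce),2.35,0.31,21.03,3.43,0.178,0.0823,13.89,1.16
Eggs,Scrambled eggs with green peppers,Stir-frying,25.4,2.78,11.12,1.38,0.8295,0.1519,8.77,1.38
Eggs,Hard-boiled eggs,Stewing (with soy sauce),11.24,2.37,14.34,1.56,0.1613,0.0164,13.97,1.42
Eggs,Fried Eggs,Stir-frying,24.56,2.18,13.9,0.58,0.1788,0.0142,11.65,2.51
Pakchoi cabbage,Stir Fried Pakchoi cabbage,Stir-frying,7.13,2.8,1.98,0.09,0.8767,0.1747,17.89,4
Pakchoi cabbage,Quick-boiled Pakchoi cabbage,Quick-boiling,3.72,0.76,1.51,0.31,0.0805,0.0193,22.39,0.63
Potatoes,Hot and Sour Shredded Potatoes,Stir-frying,10,2.32,1.23,0.15,0.6153,0.1569,25.53,1.57
Potatoes,Baked Potatoes,Roasting,24.57,2.7,2.65,0.79,0.0076,0.0055,29.26,5.79
Potatoes,French fries (chips),Deep-frying,7.38,0.44,2.73,0.81,0.0141,0.0071,33.56,1.72
Potatoes,boiled potatoes,Boiling,3.77,1.04,2.13,0.39,0.5337,0.2191,28.37,1.47
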