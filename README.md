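# catercalc

Nutrition calculation for cooked catering dishes.

Restaurant dishes are labeled per 100 g of the **cooked** dish, but
composition databases describe **raw** ingredients. catercalc bridges the
gap with three linked databases and a calculation engine:

1. **Composition database** — per-100 g edible-portion nutrient values of
   raw ingredients, organised as general category → subclass, with
   unweighted group means ("representative values") standing in for
   unknown varieties of a known food type.
2. **Raw-to-cooked ratio database** — yield ratios
   r = raw edible mass / cooked mass per (food category, cooking method),
   used to estimate the cooked dish weight when it was not measured.
3. **Correction-factor database** — multiplicative factors per
   (category, method, nutrient), derived from paired model-calculated and
   laboratory-detected dish values: cells whose calculated/detected ratio
   is ≤ 0.5 or ≥ 2 flag a systematic cooking effect, and the factor is
   the mean of detected/calculated over the key's cells.

The engine computes, for a dish with ingredient masses mᵢ and raw
compositions cᵢ (g/100 g),

    C = [ Σᵢ cᵢ · mᵢ/100 · k(category, method, nutrient) + seasoning fat/sodium ] / W × 100

where W is the measured cooked weight or (Σ input mass)/r, then adds
energy (defaults 17/37/17 kJ/g for protein/fat/carbohydrate) and NRV%
(share of a daily reference amount) to produce a label. The package ships
plain-CSV reference tables from a published cooking study of common
Chinese dishes — 44 measured yield ratios and 48 dishes' paired
calculated/detected macronutrient values — plus a seeded synthetic-data
generator for statistical tests.

## Worked example

A recipe is a small JSON file:

```json
{
  "name": "chicken fried rice",
  "cooking_method": "Stir-frying",
  "ingredients": [
    {"food": "rice_01", "raw_mass_g": 150},
    {"food": "chk_01", "raw_mass_g": 100}
  ],
  "seasonings": [
    {"kind": "oil", "mass_g": 15},
    {"kind": "salt", "mass_g": 3},
    {"kind": "soy_sauce", "mass_g": 10}
  ]
}
```

With a composition CSV holding the two ingredients (raw rice: protein
7.4, fat 0.8, carbohydrate 77.2, sodium 0.004 g/100 g; raw chicken
breast: 19.4 / 5.0 / 2.5 / 0.063):

```
$ catercalc label fried_rice.json --db composition.csv
Nutrition label: chicken fried rice (stir_frying, 579.2 g cooked, weight estimated)
Item             per 100 g    NRV%
Energy              572 kJ      7%
Protein              5.3 g      9%
Fat                  3.7 g      6%
Carbohydrate        20.4 g      7%
Sodium            315.6 mg     16%
```

Reading the numbers: no cooked weight was given, so the engine took the
main ingredient (rice, 150 g edible), looked up the stir-fried-rice yield
ratio 0.48 from the packaged table, and estimated the cooked weight as
(150 + 100 + 28 g seasonings) / 0.48 = 579.2 g. The 15 g of oil
contributes 15 × 0.999 g fat; salt and soy sauce contribute
3 × 0.393 + 10 × 0.058 = 1.76 g sodium, which is most of the
315.6 mg/100 g. Energy is 17 · 5.3 + 37 · 3.7 + 17 · 20.4 ≈ 572 kJ, and
each NRV% column entry is the per-100 g amount over its daily reference
(e.g. sodium 315.6 mg / 2000 mg ≈ 16%).

Deriving and checking correction factors from the packaged paired tables:

```
$ catercalc derive-corrections --out factors.csv
$ catercalc validate
         fat  MAE    7.657 ->    3.429   MAPE     71.2% ->     23.7%
     protein  MAE    6.817 ->    3.411   MAPE     49.2% ->     19.1%
carbohydrate  MAE   12.559 ->    4.341   MAPE     72.7% ->     21.2%
      sodium  MAE    0.270 ->    0.046   MAPE     73.4% ->     10.6%
     overall  MAE    6.826 ->    2.807   MAPE     66.6% ->     18.6%
```

i.e. applying the derived factors cuts the mean absolute percentage error
of calculated vs laboratory-detected values from 66.6% to 18.6% on the
packaged data. Passing `--corrections factors.csv` to `catercalc label`
applies the same factors to new recipes. Other subcommands: `ratio-table`
(the screened calculated/detected ratio table, `*` marking flagged
cells), `repvalues`, `fixtures`, `synth`. The same functionality is
available as a library (`import catercalc`); see `docs/methods.md` for
the model in full.

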