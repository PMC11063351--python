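"""The label calculation: summation, conservation, energy and NRV."""

import numpy as np
import pytest

import catercalc as cc
from catercalc.errors import ConfigError, DomainError, MissingRatioError


def single_line_dish(mass=200.0, cooked=None, method=cc.CookingMethod.STEAMING):
    return cc.Dish("test dish", method, (cc.RecipeLine("rice_01", mass),),
                   measured_cooked_weight_g=cooked)


class TestSumNutrients:
    def test_two_lines_sum(self):
        total = cc.sum_nutrients([
            (cc.NutrientVector(fat=10), 100.0),
            (cc.NutrientVector(fat=20), 100.0),
        ])
        assert total.fat == pytest.approx(30.0)

    def test_empty_is_zero(self):
        assert cc.sum_nutrients([]) == cc.NutrientVector.zero()

    def test_single_line_scaling(self):
        total = cc.sum_nutrients([(cc.NutrientVector(protein=20), 250.0)])
        assert total.protein == pytest.approx(50.0)


class TestComputeLabel:
    def test_measured_weight_case(self, small_db):
        res = cc.compute_label(single_line_dish(cooked=400.0), small_db)
        # 200 g edible x 7 g/100 g = 14 g over 400 g cooked
        assert res.per_100g_cooked.protein == pytest.approx(14.0 / 400.0 * 100.0)
        assert res.weight_source == "measured"

    def test_estimated_weight_closed_form(self, small_db, ratio_db):
        res = cc.compute_label(single_line_dish(), small_db, ratio_db)
        assert res.cooked_weight_g == pytest.approx(200.0 / 0.49)
        # per-100 g cooked = raw content x ratio
        assert res.per_100g_cooked.protein == pytest.approx(7.0 * 0.49)
        assert res.weight_source == "estimated"
        assert res.ratio_used.ratio == 0.49

    def test_correction_factor_scales_linearly(self, small_db, ratio_db):
        factors = cc.CorrectionDB([cc.CorrectionFactor(
            "grain", cc.CookingMethod.STEAMING, "protein", 2.0, n_support=1, active=True)])
        base = cc.compute_label(single_line_dish(), small_db, ratio_db)
        corrected = cc.compute_label(single_line_dish(), small_db, ratio_db, factors)
        assert corrected.per_100g_cooked.protein == pytest.approx(2.0 * base.per_100g_cooked.protein)
        assert corrected.per_100g_cooked.fat == pytest.approx(base.per_100g_cooked.fat)
        assert corrected.corrected and not base.corrected

    def test_seasonings_add_fat_and_sodium_only(self, small_db):
        dish = cc.Dish("seasoned", cc.CookingMethod.STIR_FRYING,
                       (cc.RecipeLine("rice_01", 100.0),),
                       seasonings=(cc.SeasoningAmount(cc.SeasoningKind.OIL, 10.0),
                                   cc.SeasoningAmount(cc.SeasoningKind.SALT, 2.0)),
                       measured_cooked_weight_g=100.0)
        plain = cc.compute_label(single_line_dish(100.0, cooked=100.0), small_db)
        res = cc.compute_label(dish, small_db)
        assert res.totals.fat - plain.totals.fat == pytest.approx(10.0 * 0.999)
        assert res.totals.sodium - plain.totals.sodium == pytest.approx(2.0 * 0.393)
        assert res.totals.protein == pytest.approx(plain.totals.protein)

    def test_sugar_carbohydrate_toggle(self, small_db):
        dish = cc.Dish("sweet", cc.CookingMethod.STIR_FRYING,
                       (cc.RecipeLine("rice_01", 100.0),),
                       seasonings=(cc.SeasoningAmount(cc.SeasoningKind.SUGAR, 10.0),),
                       measured_cooked_weight_g=100.0)
        on = cc.compute_label(dish, small_db)
        off = cc.compute_label(dish, small_db, include_sugar_carbohydrate=False)
        assert on.totals.carbohydrate - off.totals.carbohydrate == pytest.approx(10.0 * 0.999)

    def test_edible_fraction_applied(self, small_db):
        # potato record has edible fraction 0.94
        dish = cc.Dish("boiled potato", cc.CookingMethod.BOILING,
                       (cc.RecipeLine("pot_01", 100.0),), measured_cooked_weight_g=100.0)
        res = cc.compute_label(dish, small_db)
        assert res.totals.protein == pytest.approx(2.0 * 0.94)
        override = cc.Dish("boiled potato", cc.CookingMethod.BOILING,
                           (cc.RecipeLine("pot_01", 100.0, edible_fraction=0.5),),
                           measured_cooked_weight_g=100.0)
        assert cc.compute_label(override, small_db).totals.protein == pytest.approx(1.0)

    def test_missing_ratio_without_measured_weight(self, small_db, ratio_db):
        dish = cc.Dish("roast chicken", cc.CookingMethod.BOILING,
                       (cc.RecipeLine("chk_01", 100.0),))
        with pytest.raises(MissingRatioError):
            cc.compute_label(dish, small_db, ratio_db)
        res = cc.compute_label(dish, small_db, ratio_db, assume_unity_ratio=True)
        assert res.cooked_weight_g == pytest.approx(100.0)

    def test_conservation_and_homogeneity_on_random_dishes(self, small_db, ratio_db):
        """per-100 g x cooked weight / 100 == nutrient totals; scale invariance."""
        rng = np.random.default_rng(7)
        ids = [r.id for r in small_db.records]
        for _ in range(200):
            n = rng.integers(1, 4)
            lines = tuple(cc.RecipeLine(rng.choice(ids), float(rng.uniform(10, 500)))
                          for _ in range(n))
            measured = float(rng.uniform(50, 1000))
            dish = cc.Dish("random", cc.CookingMethod.STEAMING, lines,
                           measured_cooked_weight_g=measured)
            res = cc.compute_label(dish, small_db, ratio_db)
            expected = cc.sum_nutrients([
                (small_db.resolve(l.ingredient_ref).nutrients,
                 l.raw_mass_g * (small_db.resolve(l.ingredient_ref).edible_fraction or 1.0))
                for l in lines
            ])
            for field in cc.MODELED_NUTRIENTS:
                lhs = getattr(res.per_100g_cooked, field) * res.cooked_weight_g / 100.0
                assert lhs == pytest.approx(getattr(expected, field), abs=1e-9)
            k = float(rng.uniform(0.5, 3.0))
            scaled = cc.Dish("scaled", cc.CookingMethod.STEAMING,
                             tuple(cc.RecipeLine(l.ingredient_ref, l.raw_mass_g * k) for l in lines),
                             measured_cooked_weight_g=measured * k)
            res_k = cc.compute_label(scaled, small_db, ratio_db)
            for field in cc.MODELED_NUTRIENTS:
                assert getattr(res_k.per_100g_cooked, field) == pytest.approx(
                    getattr(res.per_100g_cooked, field), rel=1e-12)

    def test_recipe_json_round_trip(self, small_db, ratio_db):
        dish = cc.Dish.from_json("""
        {"name": "fried rice", "cooking_method": "Stir-frying",
         "ingredients": [{"food": "rice_01", "raw_mass_g": 150},
                         {"food": "unknown egg", "raw_mass_g": 50, "subclass": "rice"}],
         "seasonings": [{"kind": "oil", "mass_g": 15}, {"kind": "salt", "mass_g": 3}],
         "cooked_weight_g": 350}
        """)
        res = cc.compute_label(dish, small_db, ratio_db)
        assert res.weight_source == "measured"
        assert res.resolution_levels["unknown egg"] == "subclass"


class TestEnergy:
    def test_default_kj_factors(self):
        assert cc.energy_of(cc.NutrientVector(protein=10)).kj == pytest.approx(170.0)
        assert cc.energy_of(cc.NutrientVector.zero()).kj == 0.0

    def test_kcal_factor_config(self):
        ev = cc.energy_of(cc.NutrientVector(protein=10, fat=5, carbohydrate=20),
                          cc.EnergyFactors(4, 9, 4, unit="kcal"))
        assert ev.kcal == pytest.approx(165.0)
        assert ev.kj == pytest.approx(165.0 * 4.184)

    def test_linearity(self):
        nv = cc.NutrientVector(protein=3, fat=2, carbohydrate=7)
        assert cc.energy_of(nv.scale(2.5)).kj == pytest.approx(2.5 * cc.energy_of(nv).kj)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            cc.energy_of(cc.NutrientVector(fat=-1, protein=0, carbohydrate=0))


class TestNrvPercent:
    def test_sodium_unit_harmonization(self):
        out = cc.nrv_percent(cc.NutrientVector(sodium=1.0))
        assert out["sodium"] == pytest.approx(50.0)  # 1000 mg of a 2000 mg reference

    def test_protein_and_zero(self):
        out = cc.nrv_percent(cc.NutrientVector(protein=30.0))
        assert out["protein"] == pytest.approx(50.0)
        assert cc.nrv_percent(cc.NutrientVector.zero())["fat"] == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ConfigError):
            cc.NrvReference(protein_g=0.0)

    def test_linearity(self):
        nv = cc.NutrientVector(fat=5, protein=10, carbohydrate=20, sodium=0.5)
        doubled = cc.nrv_percent(nv.scale(2.0))
        single = cc.nrv_percent(nv)
        assert all(doubled[k] == pytest.approx(2 * single[k]) for k in single)


class TestLabelOutput:
    def test_text_and_json_agree(self, small_db):
        res = cc.compute_label(single_line_dish(cooked=400.0), small_db)
        data = cc.label_dict(res)
        text = cc.label_text(res)
        assert f"{data['per_100g']['protein_g']} g" in text
        assert data["per_100g"]["sodium_mg"] == pytest.approx(
            res.per_100g_cooked.sodium * 1000, abs=0.05)
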