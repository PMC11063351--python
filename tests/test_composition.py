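"""Composition database: loading, representative values, resolution, proximates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import catercalc as cc
from catercalc.errors import (
    DomainError,
    DuplicateIdError,
    InconsistentProximatesError,
    RecordValidationError,
    SchemaError,
    UnresolvableIngredientError,
)


class TestReadCompositionTable:
    def test_valid_rows_load_identically(self, small_composition_frame):
        records = cc.read_composition_table(small_composition_frame)
        assert len(records) == len(small_composition_frame)
        assert records[0].id == "rice_01"
        assert records[0].nutrients.protein == 7.0

    def test_duplicate_id_rejected(self, small_composition_frame):
        frame = small_composition_frame.copy()
        frame.loc[1, "id"] = "rice_01"
        with pytest.raises(DuplicateIdError, match="rice_01"):
            cc.read_composition_table(frame)

    def test_negative_nutrient_names_row_and_field(self, small_composition_frame):
        frame = small_composition_frame.copy()
        frame.loc[2, "fat_g"] = -1.0
        with pytest.raises(RecordValidationError, match=r"row 4.*fat"):
            cc.read_composition_table(frame)

    def test_missing_column_is_schema_error(self, small_composition_frame):
        with pytest.raises(SchemaError, match="subclass"):
            cc.read_composition_table(small_composition_frame.drop(columns=["subclass"]))

    def test_sodium_mg_accepted_but_not_both(self, small_composition_frame):
        frame = small_composition_frame.rename(columns={"sodium_g": "sodium_mg"})
        frame["sodium_mg"] = frame["sodium_mg"] * 1000.0
        records = cc.read_composition_table(frame)
        assert records[0].nutrients.sodium == pytest.approx(0.004)
        frame["sodium_g"] = 0.004
        with pytest.raises(SchemaError, match="exactly one"):
            cc.read_composition_table(frame)

    def test_bad_edible_fraction_rejected(self, small_composition_frame):
        frame = small_composition_frame.copy()
        frame.loc[0, "edible_fraction"] = 1.5
        with pytest.raises(RecordValidationError, match="edible_fraction"):
            cc.read_composition_table(frame)

    def test_round_trip_through_frame(self, small_composition_frame):
        records = cc.read_composition_table(small_composition_frame)
        again = cc.read_composition_table(cc.records_to_frame(records))
        assert again == records


class TestRepresentativeValues:
    def test_mean_of_two(self, small_db):
        rep = {r.subclass: r for r in small_db.subclass_representatives}["rice"]
        assert rep.nutrients.protein == pytest.approx((7.0 + 8.0) / 2)
        assert rep.n_members == 2

    def test_singleton_equals_member(self, small_db):
        rep = {r.subclass: r for r in small_db.subclass_representatives}["potato"]
        assert rep.nutrients == small_db.records[3].nutrients
        assert rep.n_members == 1

    def test_empty_input_errors(self):
        with pytest.raises(DomainError):
            cc.representative_values([])

    def test_matches_brute_force_mean_and_permutation_invariant(self):
        """Group means equal an independent direct-summation mean, and are
        exactly order-independent for integer-valued inputs."""
        rng = np.random.default_rng(20260926)
        records = []
        mu = {"fat": 120.0, "protein": 200.0, "carbohydrate": 30.0, "sodium": 6.0}
        for i in range(200):
            draws = {k: float(np.round(np.clip(rng.normal(m, 0.1 * m), 0, None)))
                     for k, m in mu.items()}
            records.append(cc.IngredientRecord(
                id=f"r{i}", name=f"r{i}", general_category="meat", subclass="chicken",
                edible_fraction=1.0, nutrients=cc.NutrientVector(**draws),
            ))
        (rep,) = cc.representative_values(records)
        for nutrient, m in mu.items():
            brute = sum(getattr(r.nutrients, nutrient) for r in records) / len(records)
            assert getattr(rep.nutrients, nutrient) == brute
            se = 0.1 * m / np.sqrt(len(records))
            assert abs(brute - m) < 3 * se + 0.5  # 0.5 covers integer rounding
        shuffled = list(records)
        rng.shuffle(shuffled)
        (rep2,) = cc.representative_values(shuffled)
        assert rep2.nutrients == rep.nutrients

    def test_missing_optional_nutrient_skipped_with_count(self):
        records = [
            cc.IngredientRecord("a", "a", "g", "s", 1.0, cc.NutrientVector(1, 1, 1, 0, water=50.0)),
            cc.IngredientRecord("b", "b", "g", "s", 1.0, cc.NutrientVector(3, 1, 1, 0)),
        ]
        (rep,) = cc.representative_values(records)
        assert rep.nutrients.water == 50.0
        assert rep.n_per_nutrient["water"] == 1
        assert rep.n_per_nutrient["fat"] == 2
        assert rep.nutrients.fat == 2.0


class TestResolveIngredient:
    def test_exact_match_returns_stored_record(self, small_db):
        res = small_db.resolve("rice_01")
        assert res.level == "exact"
        assert res.nutrients is small_db.records[0].nutrients
        assert res.edible_fraction == 1.0

    def test_unknown_variety_falls_back_to_subclass_mean(self, small_db):
        res = small_db.resolve("purple rice", subclass="rice")
        assert res.level == "subclass"
        rep = {r.subclass: r for r in small_db.subclass_representatives}["rice"]
        assert res.nutrients is rep.nutrients  # stored object, nothing fabricated

    def test_category_fallback(self, small_db):
        res = small_db.resolve("taro", general_category="vegetable")
        assert res.level == "category"

    def test_no_match_lists_suggestions(self, small_db):
        with pytest.raises(UnresolvableIngredientError, match="nearest known"):
            small_db.resolve("dragonfruit")


class TestCarbohydrateByDifference:
    @pytest.mark.parametrize("args, expected", [
        ((100, 70, 1, 10, 5), 14.0),
        ((100, 0, 0, 0, 0), 100.0),
        ((250, 100, 2, 40, 30), 78.0),
    ])
    def test_direct_formula(self, args, expected):
        assert cc.carbohydrate_by_difference(*args) == pytest.approx(expected)

    def test_small_deficit_clamped_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert cc.carbohydrate_by_difference(100, 70.2, 1, 24, 5) == 0.0
        assert "clamped" in caplog.text

    def test_large_deficit_is_error(self):
        with pytest.raises(InconsistentProximatesError):
            cc.carbohydrate_by_difference(100, 80, 2, 24, 5)

    def test_negative_argument_rejected(self):
        with pytest.raises(DomainError):
            cc.carbohydrate_by_difference(100, -1, 0, 0, 0)

    @given(
        total=st.floats(50, 500),
        w=st.floats(0, 100),
        a=st.floats(0, 5),
        p=st.floats(0, 40),
        f=st.floats(0, 40),
    )
    def test_mass_balance_when_not_clamped(self, total, w, a, p, f):
        """carb + components reconstructs the total whenever no clamping occurs."""
        if total - w - a - p - f >= 0:
            carb = cc.carbohydrate_by_difference(total, w, a, p, f)
            assert carb + w + a + p + f == pytest.approx(total, abs=1e-9)


class TestNutrientVector:
    def test_proximate_sum_invariant(self):
        with pytest.raises(RecordValidationError, match="proximate sum"):
            cc.NutrientVector(fat=10, protein=10, carbohydrate=50, sodium=0,
                              water=30, ash=2).validate()
        # exactly at tolerance passes
        cc.NutrientVector(fat=10, protein=10, carbohydrate=50, sodium=0,
                          water=29.5, ash=1.0).validate()
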