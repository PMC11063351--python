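"""The calculation model proper: from recipe to per-100 g-cooked label.

For each recipe line the edible raw mass (purchased mass x edible
fraction) is multiplied by the ingredient's per-100 g raw nutrient content
and, when a correction database is supplied, by the multiplicative
correction factor for that ingredient's (category, cooking method,
nutrient).  Seasoning fat and sodium (and optionally sugar carbohydrate)
are added as absolute masses.  The total is divided by the cooked dish
weight — measured when available, otherwise raw input mass divided by the
main ingredient's raw-to-cooked ratio — and scaled to 100 g.  Nutrients
are conserved from raw to cooked: for a single-ingredient dish with
estimated weight this reduces to the closed form

    per-100 g cooked = raw content per 100 g x ratio x correction factor.

Energy uses configurable per-gram conversion factors (defaults 17/37/17
kJ/g for protein/fat/carbohydrate, the Chinese labeling convention), and
NRV% expresses each nutrient as a percentage of a daily reference amount.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Mapping, Sequence

from .composition import MODELED_NUTRIENTS, CompositionDB, NutrientVector, ResolvedIngredient
from .cooking import (
    CookingMethod,
    RatioDB,
    RawCookedRatio,
    SeasoningAmount,
    SeasoningKind,
    estimate_cooked_weight,
    seasoning_nutrients,
)
from .errors import ConfigError, DegenerateDishError, DomainError, MissingRatioError

if TYPE_CHECKING:  # pragma: no cover
    from .correction import CorrectionDB

logger = logging.getLogger(__name__)

KJ_PER_KCAL = 4.184


# ---------------------------------------------------------------------------
# Recipe types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecipeLine:
    """One ingredient of a recipe, by purchased (as-bought) raw mass."""

    ingredient_ref: str
    raw_mass_g: float
    edible_fraction: float | None = None  # overrides the record's value
    subclass: str | None = None  # declared fallback for unknown varieties
    general_category: str | None = None

    def __post_init__(self) -> None:
        if self.raw_mass_g < 0:
            raise DomainError(f"raw_mass_g must be >= 0, got {self.raw_mass_g!r}")
        if self.edible_fraction is not None and not (0.0 < self.edible_fraction <= 1.0):
            raise DomainError(f"edible_fraction must lie in (0, 1], got {self.edible_fraction!r}")


@dataclass(frozen=True)
class Dish:
    name: str
    method: CookingMethod
    lines: tuple[RecipeLine, ...]
    seasonings: tuple[SeasoningAmount, ...] = ()
    measured_cooked_weight_g: float | None = None

    def __post_init__(self) -> None:
        if len(self.lines) < 1:
            raise DomainError("a dish needs at least one recipe line")
        if self.measured_cooked_weight_g is not None and not self.measured_cooked_weight_g > 0:
            raise DomainError(
                f"measured cooked weight must be > 0 when given, got {self.measured_cooked_weight_g!r}"
            )

    @classmethod
    def from_json(cls, source: str | dict) -> "Dish":
        """Parse the recipe JSON format:

        ``{name, cooking_method, ingredients: [{food, raw_mass_g,
        edible_fraction?, subclass?, category?}], seasonings: [{kind,
        mass_g}], cooked_weight_g?}``
        """
        data = json.loads(source) if isinstance(source, str) else source
        lines = tuple(
            RecipeLine(
                ingredient_ref=item["food"],
                raw_mass_g=float(item["raw_mass_g"]),
                edible_fraction=item.get("edible_fraction"),
                subclass=item.get("subclass"),
                general_category=item.get("category"),
            )
            for item in data.get("ingredients", [])
        )
        seasonings = tuple(
            SeasoningAmount(SeasoningKind(s["kind"]), float(s["mass_g"]))
            for s in data.get("seasonings", [])
        )
        return cls(
            name=data.get("name", "dish"),
            method=CookingMethod.parse(data["cooking_method"]),
            lines=lines,
            seasonings=seasonings,
            measured_cooked_weight_g=data.get("cooked_weight_g"),
        )


# ---------------------------------------------------------------------------
# Energy and NRV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyFactors:
    """Per-gram energy conversion factors.

    ``unit`` states which unit the factors are expressed in; the other unit
    is derived through 1 kcal = 4.184 kJ.  Defaults are the kJ factors used
    on Chinese nutrition labels; the classic 4/9/4 kcal factors are a
    one-line config away.
    """

    protein: float = 17.0
    fat: float = 37.0
    carbohydrate: float = 17.0
    unit: Literal["kJ", "kcal"] = "kJ"

    def __post_init__(self) -> None:
        if min(self.protein, self.fat, self.carbohydrate) < 0:
            raise ConfigError("energy factors must be >= 0")
        if self.unit not in ("kJ", "kcal"):
            raise ConfigError(f"energy unit must be 'kJ' or 'kcal', got {self.unit!r}")


@dataclass(frozen=True)
class EnergyValue:
    kj: float
    kcal: float


def energy_of(nv: NutrientVector, factors: EnergyFactors | None = None) -> EnergyValue:
    """Energy of a nutrient vector (same basis as the vector: per 100 g or total)."""
    factors = factors or EnergyFactors()
    for name in ("protein", "fat", "carbohydrate"):
        if getattr(nv, name) < 0:
            raise DomainError(f"negative {name} in energy computation")
    raw = factors.protein * nv.protein + factors.fat * nv.fat + factors.carbohydrate * nv.carbohydrate
    if factors.unit == "kJ":
        return EnergyValue(kj=raw, kcal=raw / KJ_PER_KCAL)
    return EnergyValue(kj=raw * KJ_PER_KCAL, kcal=raw)


@dataclass(frozen=True)
class NrvReference:
    """Daily reference amounts used for the NRV% column of a label."""

    energy_kj: float = 8400.0
    protein_g: float = 60.0
    fat_g: float = 60.0
    carbohydrate_g: float = 300.0
    sodium_mg: float = 2000.0

    def __post_init__(self) -> None:
        if min(self.energy_kj, self.protein_g, self.fat_g, self.carbohydrate_g, self.sodium_mg) <= 0:
            raise ConfigError("all NRV reference amounts must be > 0")


def nrv_percent(
    nv: NutrientVector,
    ref: NrvReference | None = None,
    energy_kj: float | None = None,
) -> dict[str, float]:
    """Per-nutrient percentage of the daily reference amount.

    Sodium is converted from g to mg before dividing.  When ``energy_kj``
    is given an ``energy`` entry is included.
    """
    ref = ref or NrvReference()
    out = {
        "fat": 100.0 * nv.fat / ref.fat_g,
        "protein": 100.0 * nv.protein / ref.protein_g,
        "carbohydrate": 100.0 * nv.carbohydrate / ref.carbohydrate_g,
        "sodium": 100.0 * (nv.sodium * 1000.0) / ref.sodium_mg,
    }
    if energy_kj is not None:
        out["energy"] = 100.0 * energy_kj / ref.energy_kj
    return out


# ---------------------------------------------------------------------------
# Summation and the label computation
# ---------------------------------------------------------------------------

def sum_nutrients(resolved_lines: Sequence[tuple[NutrientVector, float]]) -> NutrientVector:
    """Sum of per-100 g nutrient vectors weighted by edible raw mass (g).

    Returns absolute grams: sum_i nutrients_i x mass_i / 100.
    """
    total = NutrientVector.zero()
    for per100, mass_g in resolved_lines:
        if mass_g < 0:
            raise DomainError("edible mass must be >= 0")
        total = total.add(per100.scale(mass_g / 100.0))
    return total


@dataclass(frozen=True)
class CalcResult:
    """Computed label for one dish."""

    dish_name: str
    method: CookingMethod
    totals: NutrientVector                      # absolute g in the whole dish
    per_100g_cooked: NutrientVector
    cooked_weight_g: float
    weight_source: Literal["measured", "estimated"]
    energy_per_100g: EnergyValue
    nrv_percent: Mapping[str, float]
    corrected: bool
    applied_factors: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    ratio_used: RawCookedRatio | None = None
    resolution_levels: Mapping[str, str] = field(default_factory=dict)


def compute_label(
    dish: Dish,
    db: CompositionDB,
    ratios: RatioDB | None = None,
    corrections: "CorrectionDB | None" = None,
    seasoning_composition: Mapping[SeasoningKind, NutrientVector] | None = None,
    *,
    energy_factors: EnergyFactors | None = None,
    nrv: NrvReference | None = None,
    oil_uptake_fraction: float = 1.0,
    include_sugar_carbohydrate: bool = True,
    assume_unity_ratio: bool = False,
    nrv_basis: Literal["per_100g", "totals"] = "per_100g",
) -> CalcResult:
    """Run the full calculation model for one dish.

    Correction factors, when supplied, multiply each line's contribution
    per (ingredient category, cooking method, nutrient).  Seasonings add
    fat and sodium in absolute grams (sugar carbohydrate included unless
    disabled).  The cooked weight is the measured weight when given,
    otherwise (total edible raw mass + seasoning mass) divided by the
    main ingredient's raw-to-cooked ratio.
    """
    # Resolve lines and collect edible masses.
    resolved: list[tuple[RecipeLine, ResolvedIngredient, float]] = []
    levels: dict[str, str] = {}
    for line in dish.lines:
        if line.raw_mass_g == 0:
            continue
        res = db.resolve(line.ingredient_ref, subclass=line.subclass,
                         general_category=line.general_category)
        fraction = line.edible_fraction
        if fraction is None:
            fraction = res.edible_fraction if res.edible_fraction is not None else 1.0
        resolved.append((line, res, line.raw_mass_g * fraction))
        levels[line.ingredient_ref] = res.level

    # Nutrient totals, with per-line correction factors.
    applied: dict[tuple[str, str, str], float] = {}
    totals = NutrientVector.zero()
    for line, res, edible_mass in resolved:
        contribution = res.nutrients.scale(edible_mass / 100.0).modeled()
        if corrections is not None:
            for nutrient in MODELED_NUTRIENTS:
                factor = corrections.get(res.general_category, dish.method, nutrient)
                if factor != 1.0:
                    applied[(res.general_category, dish.method.value, nutrient)] = factor
                contribution[nutrient] *= factor
        totals = totals.add(NutrientVector(**contribution))

    seasoning_total = seasoning_nutrients(
        dish.seasonings, seasoning_composition, oil_uptake_fraction=oil_uptake_fraction
    )
    totals = totals.add(NutrientVector(
        fat=seasoning_total.fat,
        sodium=seasoning_total.sodium,
        carbohydrate=seasoning_total.carbohydrate if include_sugar_carbohydrate else 0.0,
    ))

    # Cooked weight: measured wins; otherwise derive from the yield ratio of
    # the main ingredient (largest edible raw mass).
    ratio_used: RawCookedRatio | None = None
    if dish.measured_cooked_weight_g is not None:
        cooked_weight = dish.measured_cooked_weight_g
        source: Literal["measured", "estimated"] = "measured"
    else:
        if not resolved:
            raise DegenerateDishError(f"dish {dish.name!r} has no non-zero recipe lines")
        if ratios is None:
            raise ConfigError("a RatioDB is required when no measured cooked weight is given")
        _, main, _ = max(resolved, key=lambda item: item[2])
        try:
            ratio_used = ratios.lookup(main.subclass or main.general_category, dish.method,
                                       assume_unity=False)
        except MissingRatioError:
            ratio_used = ratios.lookup(main.general_category, dish.method,
                                       assume_unity=assume_unity_ratio)
        total_input = sum(mass for _, _, mass in resolved) + sum(s.mass_g for s in dish.seasonings)
        cooked_weight = estimate_cooked_weight(total_input, ratio_used.ratio)
        source = "estimated"
    if not cooked_weight > 0:
        raise DegenerateDishError(f"dish {dish.name!r}: cooked weight is {cooked_weight!r}")

    per100 = totals.scale(100.0 / cooked_weight)
    energy = energy_of(per100, energy_factors)
    if nrv_basis == "per_100g":
        nrv_out = nrv_percent(per100, nrv, energy_kj=energy.kj)
    elif nrv_basis == "totals":
        nrv_out = nrv_percent(totals, nrv, energy_kj=energy_of(totals, energy_factors).kj)
    else:
        raise ConfigError(f"nrv_basis must be 'per_100g' or 'totals', got {nrv_basis!r}")

    return CalcResult(
        dish_name=dish.name,
        method=dish.method,
        totals=totals,
        per_100g_cooked=per100,
        cooked_weight_g=cooked_weight,
        weight_source=source,
        energy_per_100g=energy,
        nrv_percent=nrv_out,
        corrected=bool(applied),
        applied_factors=applied,
        ratio_used=ratio_used,
        resolution_levels=levels,
    )


# ---------------------------------------------------------------------------
# Label rendering
# ---------------------------------------------------------------------------

def label_dict(result: CalcResult) -> dict:
    """JSON-ready label; display rounding is 1 dp for g, integers for kJ/NRV%."""
    nv = result.per_100g_cooked
    return {
        "dish": result.dish_name,
        "cooking_method": result.method.value,
        "cooked_weight_g": round(result.cooked_weight_g, 1),
        "weight_source": result.weight_source,
        "corrected": result.corrected,
        "per_100g": {
            "energy_kj": round(result.energy_per_100g.kj),
            "energy_kcal": round(result.energy_per_100g.kcal),
            "fat_g": round(nv.fat, 1),
            "protein_g": round(nv.protein, 1),
            "carbohydrate_g": round(nv.carbohydrate, 1),
            "sodium_mg": round(nv.sodium * 1000.0, 1),
        },
        "nrv_percent": {key: round(value) for key, value in result.nrv_percent.items()},
    }


def label_text(result: CalcResult) -> str:
    """Aligned nutrition-facts text table (per 100 g)."""
    data = label_dict(result)
    p, n = data["per_100g"], data["nrv_percent"]
    rows = [
        ("Energy", f"{p['energy_kj']} kJ", f"{n.get('energy', 0)}%"),
        ("Protein", f"{p['protein_g']} g", f"{n['protein']}%"),
        ("Fat", f"{p['fat_g']} g", f"{n['fat']}%"),
        ("Carbohydrate", f"{p['carbohydrate_g']} g", f"{n['carbohydrate']}%"),
        ("Sodium", f"{p['sodium_mg']} mg", f"{n['sodium']}%"),
    ]
    width = max(len(r[0]) for r in rows)
    lines = [
        f"Nutrition label: {data['dish']} ({data['cooking_method']}, "
        f"{data['cooked_weight_g']} g cooked, weight {data['weight_source']})",
        f"{'Item'.ljust(width)}  {'per 100 g':>12}  {'NRV%':>6}",
    ]
    for name, amount, pct in rows:
        lines.append(f"{name.ljust(width)}  {amount:>12}  {pct:>6}")
    if result.corrected:
        lines.append("(cooking-method correction factors applied)")
    return "\n".join(lines)
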