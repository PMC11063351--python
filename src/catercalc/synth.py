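"""Seeded synthetic data: composition tables and paired calculated/detected sets.

The composition generator emulates a food composition table for the
ingredient types the model targets (rice, noodles, chicken breast, pork
belly, grass carp, eggs, pakchoi, potato, ...), drawing per-100 g raw
nutrient values from per-subclass normal distributions truncated at zero.
The stated means are realistic raw-ingredient compositions; they are a
synthetic stand-in for a national food composition table, not transcribed
from one.  Water is filled by difference so each row satisfies the
proximate-sum invariant exactly.

The paired generator produces dish-level calculated values with a known
multiplicative bias between calculated and detected
(detected = calculated / bias x (1 + noise)), which lets factor-recovery
tests check the derivation pipeline against a closed-form truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import MODELED_NUTRIENTS
from .cooking import CookingMethod
from .errors import ConfigError

#: Default per-subclass raw composition (g/100 g edible): mean values,
#: plus the general category and edible fraction.  SDs default to 8% of
#: the mean (see SyntheticSpec).
DEFAULT_SUBCLASSES: dict[str, dict] = {
    "rice":           {"category": "grain",     "edible_fraction": 1.00, "protein": 7.4,  "fat": 0.8,  "carbohydrate": 77.2, "sodium": 0.004, "ash": 0.6},
    "noodles":        {"category": "grain",     "edible_fraction": 1.00, "protein": 11.2, "fat": 1.5,  "carbohydrate": 73.6, "sodium": 0.003, "ash": 0.9},
    "chicken breast": {"category": "meat",      "edible_fraction": 1.00, "protein": 19.4, "fat": 5.0,  "carbohydrate": 2.5,  "sodium": 0.063, "ash": 1.0},
    "chicken leg":    {"category": "meat",      "edible_fraction": 0.69, "protein": 16.0, "fat": 13.0, "carbohydrate": 0.4,  "sodium": 0.072, "ash": 0.9},
    "pork belly":     {"category": "meat",      "edible_fraction": 1.00, "protein": 13.6, "fat": 37.0, "carbohydrate": 0.8,  "sodium": 0.059, "ash": 0.7},
    "pork leg":       {"category": "meat",      "edible_fraction": 0.75, "protein": 17.9, "fat": 20.8, "carbohydrate": 0.9,  "sodium": 0.057, "ash": 0.8},
    "beef brisket":   {"category": "meat",      "edible_fraction": 1.00, "protein": 19.0, "fat": 17.0, "carbohydrate": 0.6,  "sodium": 0.060, "ash": 0.9},
    "beef tendon":    {"category": "meat",      "edible_fraction": 1.00, "protein": 20.0, "fat": 6.0,  "carbohydrate": 1.0,  "sodium": 0.050, "ash": 1.0},
    "leg of lamb":    {"category": "meat",      "edible_fraction": 0.90, "protein": 20.0, "fat": 12.0, "carbohydrate": 0.7,  "sodium": 0.060, "ash": 0.9},
    "grass carp":     {"category": "fish",      "edible_fraction": 0.58, "protein": 16.6, "fat": 5.2,  "carbohydrate": 0.5,  "sodium": 0.046, "ash": 1.1},
    "hairtail":       {"category": "fish",      "edible_fraction": 0.76, "protein": 17.7, "fat": 4.9,  "carbohydrate": 3.1,  "sodium": 0.150, "ash": 1.1},
    "shrimp":         {"category": "fish",      "edible_fraction": 0.61, "protein": 18.6, "fat": 0.8,  "carbohydrate": 2.8,  "sodium": 0.165, "ash": 1.5},
    "egg":            {"category": "egg",       "edible_fraction": 0.88, "protein": 13.3, "fat": 8.8,  "carbohydrate": 2.8,  "sodium": 0.131, "ash": 1.0},
    "pakchoi":        {"category": "vegetable", "edible_fraction": 0.85, "protein": 1.5,  "fat": 0.3,  "carbohydrate": 2.7,  "sodium": 0.055, "ash": 0.8},
    "potato":         {"category": "vegetable", "edible_fraction": 0.94, "protein": 2.0,  "fat": 0.2,  "carbohydrate": 17.2, "sodium": 0.003, "ash": 0.8},
}

#: (category, method) keys used for synthetic paired data.
DEFAULT_PAIR_KEYS: tuple[tuple[str, CookingMethod], ...] = (
    ("grain", CookingMethod.STEAMING),
    ("grain", CookingMethod.STIR_FRYING),
    ("meat", CookingMethod.STEWING),
    ("meat", CookingMethod.DEEP_FRYING),
    ("fish", CookingMethod.STEAMING),
    ("vegetable", CookingMethod.STIR_FRYING),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators.

    ``seed`` is mandatory; identical specs produce identical tables.
    ``relative_sd`` scales each nutrient mean into its between-sample SD.
    ``bias`` maps (category, method, nutrient) -> true multiplicative bias
    of calculated over detected; ``default_bias`` covers unlisted keys.
    ``noise_sd`` is the relative SD of the multiplicative detection noise.
    """

    seed: int
    subclasses: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_SUBCLASSES))
    n_per_subclass: int = 200
    relative_sd: float = 0.08
    pair_keys: Sequence[tuple[str, CookingMethod]] = DEFAULT_PAIR_KEYS
    dishes_per_key: int = 20
    default_bias: float = 1.0
    bias: Mapping[tuple[str, CookingMethod, str], float] = field(default_factory=dict)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("SyntheticSpec.seed is mandatory")
        if self.relative_sd < 0 or self.noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.n_per_subclass < 1 or self.dishes_per_key < 1:
            raise ConfigError("sample counts must be >= 1")
        if self.default_bias <= 0 or any(b <= 0 for b in self.bias.values()):
            raise ConfigError("bias factors must be > 0")

    def bias_for(self, category: str, method: CookingMethod, nutrient: str) -> float:
        return self.bias.get((category, method, nutrient), self.default_bias)


def generate_composition(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic composition table in the standard CSV schema.

    Per subclass, ``n_per_subclass`` records are drawn with each nutrient
    ~ N(mean, (relative_sd x mean)^2) truncated at 0; water is set by
    difference so proximates sum to 100 g exactly.
    """
    rng = rng or np.random.default_rng(spec.seed)
    rows = []
    for subclass, params in spec.subclasses.items():
        n = spec.n_per_subclass
        draws = {}
        for nutrient in MODELED_NUTRIENTS + ("ash",):
            mean = float(params[nutrient] if nutrient != "ash" else params.get("ash", 0.8))
            draws[nutrient] = np.clip(rng.normal(mean, spec.relative_sd * mean, size=n), 0.0, None)
        # Water by difference keeps every row's proximate sum at exactly 100 g;
        # rare draws whose macros alone exceed 100 g are rescaled onto the simplex.
        macro_sum = draws["protein"] + draws["fat"] + draws["carbohydrate"] + draws["ash"]
        over = macro_sum > 100.0
        if over.any():
            scale = 100.0 / macro_sum[over]
            for nutrient in ("protein", "fat", "carbohydrate", "ash"):
                draws[nutrient][over] *= scale
            macro_sum[over] = 100.0
        water = 100.0 - macro_sum
        slug = subclass.replace(" ", "_")
        for i in range(n):
            rows.append({
                "id": f"{slug}_{i:03d}",
                "name": f"{subclass} sample {i:03d}",
                "general_category": params["category"],
                "subclass": subclass,
                "edible_fraction": params["edible_fraction"],
                "water_g": water[i],
                "protein_g": draws["protein"][i],
                "fat_g": draws["fat"][i],
                "carbohydrate_g": draws["carbohydrate"][i],
                "ash_g": draws["ash"][i],
                "sodium_g": draws["sodium"][i],
            })
    return pd.DataFrame(rows)


#: Per-category dish-level per-100 g cooked baselines for paired generation.
_DISH_BASELINES: dict[str, dict[str, float]] = {
    "grain": {"fat": 3.0, "protein": 4.5, "carbohydrate": 50.0, "sodium": 0.2},
    "meat": {"fat": 20.0, "protein": 20.0, "carbohydrate": 8.0, "sodium": 0.45},
    "fish": {"fat": 8.0, "protein": 21.0, "carbohydrate": 14.0, "sodium": 0.55},
    "egg": {"fat": 18.0, "protein": 13.0, "carbohydrate": 10.0, "sodium": 0.35},
    "vegetable": {"fat": 6.0, "protein": 1.8, "carbohydrate": 20.0, "sodium": 0.4},
}


def generate_paired(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic (calculated, detected) wide tables with known bias.

    calculated ~ |N(baseline, 0.2 x baseline)| per nutrient (floored at
    0.01 so every cell is defined), and
    detected = calculated / bias x (1 + e), e ~ N(0, noise_sd), floored
    at 0.
    """
    rng = rng or np.random.default_rng(spec.seed)
    calc_rows, det_rows = [], []
    for category, method in spec.pair_keys:
        base = _DISH_BASELINES.get(category, _DISH_BASELINES["meat"])
        for d in range(spec.dishes_per_key):
            meta = {
                "category": category,
                "dish_name": f"{category} {method.value} dish {d:02d}",
                "method": method.value,
            }
            calc_row, det_row = dict(meta), dict(meta)
            for nutrient in MODELED_NUTRIENTS:
                calc = max(0.01, rng.normal(base[nutrient], 0.2 * base[nutrient]))
                noise = rng.normal(0.0, spec.noise_sd)
                det = max(0.0, calc / spec.bias_for(category, method, nutrient) * (1.0 + noise))
                calc_row[nutrient] = calc
                det_row[nutrient] = det
            calc_rows.append(calc_row)
            det_rows.append(det_row)
    return pd.DataFrame(calc_rows), pd.DataFrame(det_rows)


def generate_synthetic(spec: SyntheticSpec) -> dict[str, pd.DataFrame]:
    """Full synthetic bundle: composition + paired calculated/detected tables.

    Uses one generator stream seeded from ``spec.seed``, so the whole
    bundle is a deterministic function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    composition = generate_composition(spec, rng)
    calculated, detected = generate_paired(spec, rng)
    return {"composition": composition, "calculated": calculated, "detected": detected}
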