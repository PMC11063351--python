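"""Raw-to-cooked yield ratios and seasoning nutrient contributions.

The yield ratio is defined as **raw edible mass / cooked mass** for a
(food category, cooking method) pair.  A ratio below 1 means the dish
gains mass on cooking (steamed rice absorbing water, ratio 0.49); above 1
means it loses mass (roast chicken legs, 1.43).  Cooked weight is then
estimated as raw input mass divided by the ratio.

Seasonings weighed into a dish (oil, salt, soy sauce, sugar, ...) are
converted to absolute nutrient masses through a per-100 g composition
config; the defaults follow common reference compositions (salt sodium
39.3 g/100 g from NaCl stoichiometry, refined oil fat 99.9 g/100 g).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .composition import NutrientVector
from .errors import ConfigError, DomainError, MissingRatioError, SchemaError

logger = logging.getLogger(__name__)


class CookingMethod(str, enum.Enum):
    """Closed set of cooking methods the model knows about."""

    STEAMING = "steaming"
    BOILING = "boiling"
    STIR_FRYING = "stir_frying"
    DEEP_FRYING = "deep_frying"
    ROASTING = "roasting"
    STEWING = "stewing"
    QUICK_BOILING = "quick_boiling"

    @classmethod
    def parse(cls, label: "str | CookingMethod") -> "CookingMethod":
        """Normalize printed method labels to the canonical token.

        Accepts variants such as "Stewing (with soy sauce)", "Deep-frying",
        "deep frying" or "Quick-boiling".
        """
        if isinstance(label, cls):
            return label
        text = re.sub(r"\(.*?\)", "", str(label)).strip().casefold()
        token = re.sub(r"[\s\-]+", "_", text)
        try:
            return cls(token)
        except ValueError:
            known = ", ".join(m.value for m in cls)
            raise DomainError(f"unknown cooking method {label!r}; known methods: {known}") from None


@dataclass(frozen=True)
class RawCookedRatio:
    """Yield ratio entry: raw edible mass / cooked mass for (category, method)."""

    category_or_subclass: str
    method: CookingMethod
    ratio: float
    dish_name: str | None = None  # provenance (joined names when averaged)
    n_dishes: int = 1

    def __post_init__(self) -> None:
        if not (self.ratio > 0):
            raise DomainError(f"raw-to-cooked ratio must be > 0, got {self.ratio!r}")


def _norm_key(label: str) -> str:
    return re.sub(r"\s+", " ", str(label).strip().casefold())


def _key_variants(label: str) -> list[str]:
    """Lookup variants tolerating singular/plural drift (potato vs potatoes)."""
    base = _norm_key(label)
    variants = [base, base + "s", base + "es"]
    if base.endswith("es"):
        variants.append(base[:-2])
    if base.endswith("s"):
        variants.append(base[:-1])
    return variants


class RatioDB:
    """Database of raw-to-cooked ratios keyed by (category-or-subclass, method)."""

    def __init__(self, entries: Iterable[RawCookedRatio]):
        self.entries = list(entries)
        self._index: dict[tuple[str, CookingMethod], list[RawCookedRatio]] = {}
        for entry in self.entries:
            key = (_norm_key(entry.category_or_subclass), entry.method)
            self._index.setdefault(key, []).append(entry)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatioDB":
        """Build from a table with columns category[,subclass],dish_name,method,ratio.

        When a ``subclass`` column is present, entries are indexed under both
        labels.
        """
        needed = {"category", "method", "ratio"}
        if not needed.issubset(frame.columns):
            raise SchemaError(f"ratio table needs columns {sorted(needed)}, got {list(frame.columns)}")
        entries = []
        for _, row in frame.iterrows():
            method = CookingMethod.parse(row["method"])
            dish = str(row["dish_name"]) if "dish_name" in frame.columns and pd.notna(row.get("dish_name")) else None
            labels = {str(row["category"])}
            if "subclass" in frame.columns and pd.notna(row.get("subclass")):
                labels.add(str(row["subclass"]))
            for label in labels:
                entries.append(RawCookedRatio(label, method, float(row["ratio"]), dish))
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatioDB":
        return cls.from_frame(pd.read_csv(path))

    def lookup(
        self,
        category_or_subclass: str,
        method: "str | CookingMethod",
        *,
        assume_unity: bool = False,
    ) -> RawCookedRatio:
        """Return the ratio for (category, method), averaging multi-dish keys.

        A missing key raises :class:`MissingRatioError` unless
        ``assume_unity`` is set, in which case ratio 1.0 is returned with a
        warning (no mass change assumed).
        """
        method = CookingMethod.parse(method)
        for variant in _key_variants(category_or_subclass):
            hits = self._index.get((variant, method))
            if hits:
                if len(hits) == 1:
                    return hits[0]
                mean_ratio = sum(h.ratio for h in hits) / len(hits)
                names = "; ".join(h.dish_name or "?" for h in hits)
                return RawCookedRatio(hits[0].category_or_subclass, method, mean_ratio,
                                      dish_name=names, n_dishes=len(hits))
        if assume_unity:
            logger.warning("no raw-to-cooked ratio for (%s, %s); assuming 1.0",
                           category_or_subclass, method.value)
            return RawCookedRatio(category_or_subclass, method, 1.0, dish_name=None)
        raise MissingRatioError(
            f"no raw-to-cooked ratio for category {category_or_subclass!r} with method {method.value!r}"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"category": e.category_or_subclass, "dish_name": e.dish_name,
             "method": e.method.value, "ratio": e.ratio}
            for e in self.entries
        ])


def estimate_cooked_weight(total_raw_input_mass: float, ratio: float) -> float:
    """Cooked mass implied by the yield ratio: raw input mass / ratio."""
    if not ratio > 0:
        raise DomainError(f"ratio must be > 0, got {ratio!r}")
    if total_raw_input_mass < 0:
        raise DomainError(f"mass must be >= 0, got {total_raw_input_mass!r}")
    return total_raw_input_mass / ratio


# ---------------------------------------------------------------------------
# Seasonings
# ---------------------------------------------------------------------------

class SeasoningKind(str, enum.Enum):
    OIL = "oil"
    SALT = "salt"
    SOY_SAUCE = "soy_sauce"
    SUGAR = "sugar"
    VINEGAR = "vinegar"
    CHICKEN_ESSENCE = "chicken_essence"
    FERMENTED_CURD = "fermented_curd"


@dataclass(frozen=True)
class SeasoningAmount:
    kind: SeasoningKind
    mass_g: float

    def __post_init__(self) -> None:
        if self.mass_g < 0:
            raise DomainError(f"seasoning mass must be >= 0, got {self.mass_g!r}")


#: Per-100 g nutrient content of each seasoning kind (g/100 g).
DEFAULT_SEASONING_COMPOSITION: dict[SeasoningKind, NutrientVector] = {
    SeasoningKind.OIL: NutrientVector(fat=99.9),
    SeasoningKind.SALT: NutrientVector(sodium=39.3),
    SeasoningKind.SOY_SAUCE: NutrientVector(sodium=5.8),
    SeasoningKind.SUGAR: NutrientVector(carbohydrate=99.9),
    SeasoningKind.VINEGAR: NutrientVector(),
    SeasoningKind.CHICKEN_ESSENCE: NutrientVector(sodium=20.0),
    SeasoningKind.FERMENTED_CURD: NutrientVector(),
}


def load_seasoning_config(path: str | Path) -> dict[SeasoningKind, NutrientVector]:
    """Load a YAML/JSON mapping kind -> per-100 g nutrient content.

    Missing kinds keep their defaults; unknown kinds raise ConfigError.
    """
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    config = dict(DEFAULT_SEASONING_COMPOSITION)
    for kind_label, fields in raw.items():
        try:
            kind = SeasoningKind(kind_label)
        except ValueError:
            raise ConfigError(f"unknown seasoning kind {kind_label!r} in {path}") from None
        config[kind] = NutrientVector(
            fat=float(fields.get("fat_g", 0.0)),
            protein=float(fields.get("protein_g", 0.0)),
            carbohydrate=float(fields.get("carbohydrate_g", 0.0)),
            sodium=float(fields.get("sodium_g", 0.0)),
        ).validate(per_100g=False)
    return config


def seasoning_nutrients(
    seasonings: Sequence[SeasoningAmount],
    composition: Mapping[SeasoningKind, NutrientVector] | None = None,
    *,
    oil_uptake_fraction: float = 1.0,
) -> NutrientVector:
    """Absolute nutrient masses (g) contributed by weighed seasonings.

    ``oil_uptake_fraction`` scales the fat contribution of cooking oil; the
    default of 1.0 charges all added oil to the dish (oil not fully absorbed
    by the food is still counted against it).
    """
    if not (0.0 <= oil_uptake_fraction <= 1.0):
        raise ConfigError(f"oil_uptake_fraction must lie in [0, 1], got {oil_uptake_fraction!r}")
    composition = DEFAULT_SEASONING_COMPOSITION if composition is None else composition
    total = NutrientVector.zero()
    for seasoning in seasonings:
        comp = composition.get(seasoning.kind)
        if comp is None:
            raise ConfigError(f"no composition configured for seasoning kind {seasoning.kind!r}")
        uptake = oil_uptake_fraction if seasoning.kind is SeasoningKind.OIL else 1.0
        total = total.add(NutrientVector(
            fat=seasoning.mass_g * comp.fat / 100.0 * uptake,
            protein=seasoning.mass_g * comp.protein / 100.0,
            carbohydrate=seasoning.mass_g * comp.carbohydrate / 100.0,
            sodium=seasoning.mass_g * comp.sodium / 100.0,
        ))
    return total
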