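"""Raw-material composition database.

Holds per-100 g edible-portion nutrient values of raw ingredients, groups
them into a two-tier hierarchy (general category -> subclass), computes
unweighted mean "representative values" per group, and resolves recipe
ingredients against the database with an exact -> subclass -> category
fallback chain.  Also provides the carbohydrate-by-difference rule used
when a composition source reports only proximates.

Units: all nutrient fields are grams per 100 g edible portion, sodium
included (label output converts to mg where conventional).
"""

from __future__ import annotations

import difflib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .errors import (
    DomainError,
    DuplicateIdError,
    InconsistentProximatesError,
    RecordValidationError,
    SchemaError,
    UnresolvableIngredientError,
)

logger = logging.getLogger(__name__)

#: Nutrients the calculation model tracks on every record.
MODELED_NUTRIENTS: tuple[str, ...] = ("fat", "protein", "carbohydrate", "sodium")
#: Optional proximate fields carried when the source provides them.
OPTIONAL_NUTRIENTS: tuple[str, ...] = ("water", "ash")

# Proximates may overshoot 100 g by at most this much (measurement noise).
PROXIMATE_TOLERANCE_G = 0.5


@dataclass(frozen=True)
class NutrientVector:
    """Nutrient content, conventionally per 100 g but also used for absolute totals.

    ``water`` and ``ash`` are optional; when both are present the proximate
    sum fat+protein+carbohydrate+water+ash must not exceed 100 g beyond a
    0.5 g tolerance (only enforced for per-100 g vectors via ``validate``).
    """

    fat: float = 0.0
    protein: float = 0.0
    carbohydrate: float = 0.0
    sodium: float = 0.0
    water: float | None = None
    ash: float | None = None

    def validate(self, *, per_100g: bool = True, where: str = "") -> "NutrientVector":
        loc = f" ({where})" if where else ""
        for name in MODELED_NUTRIENTS + OPTIONAL_NUTRIENTS:
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value) or value < 0:
                raise RecordValidationError(f"nutrient {name!r} must be finite and >= 0, got {value!r}{loc}")
        if per_100g and self.water is not None and self.ash is not None:
            total = self.fat + self.protein + self.carbohydrate + self.water + self.ash
            if total > 100.0 + PROXIMATE_TOLERANCE_G:
                raise RecordValidationError(
                    f"proximate sum {total:.2f} g exceeds 100 g beyond {PROXIMATE_TOLERANCE_G} g tolerance{loc}"
                )
        return self

    # -- arithmetic over the four modeled nutrients --------------------------------
    def scale(self, k: float) -> "NutrientVector":
        return NutrientVector(self.fat * k, self.protein * k, self.carbohydrate * k, self.sodium * k)

    def add(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(
            self.fat + other.fat,
            self.protein + other.protein,
            self.carbohydrate + other.carbohydrate,
            self.sodium + other.sodium,
        )

    def modeled(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MODELED_NUTRIENTS}

    @staticmethod
    def zero() -> "NutrientVector":
        return NutrientVector(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class IngredientRecord:
    """One row of a food composition table: a raw ingredient, per 100 g edible."""

    id: str
    name: str
    general_category: str
    subclass: str
    edible_fraction: float
    nutrients: NutrientVector

    def validate(self) -> "IngredientRecord":
        if not self.id:
            raise RecordValidationError("record id must be non-empty")
        if not self.subclass:
            raise RecordValidationError(f"record {self.id!r}: subclass must be non-empty")
        if not (0.0 < self.edible_fraction <= 1.0):
            raise RecordValidationError(
                f"record {self.id!r}: edible_fraction must lie in (0, 1], got {self.edible_fraction!r}"
            )
        self.nutrients.validate(where=f"record {self.id!r}")
        return self


@dataclass(frozen=True)
class CategoryRepresentative:
    """Unweighted mean nutrient content of a group of ingredient records.

    ``n_per_nutrient`` records, for each nutrient, how many members carried
    that field (optional fields may be missing on some members).
    """

    general_category: str
    subclass: str | None  # None for a general-category representative
    nutrients: NutrientVector
    n_members: int
    n_per_nutrient: Mapping[str, int] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.general_category, self.subclass)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "id", "name", "general_category", "subclass", "edible_fraction",
    "water_g", "protein_g", "fat_g", "carbohydrate_g", "ash_g",
)


def read_composition_table(source: str | Path | pd.DataFrame) -> list[IngredientRecord]:
    """Read a composition table (CSV or DataFrame) into validated records.

    The header must contain ``id,name,general_category,subclass,
    edible_fraction,water_g,protein_g,fat_g,carbohydrate_g,ash_g`` plus
    exactly one of ``sodium_g`` / ``sodium_mg``.  Rows violating invariants
    raise with row-addressed diagnostics; duplicate ids raise.
    """
    frame = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"composition table is missing required columns: {', '.join(missing)}")
    has_g, has_mg = "sodium_g" in frame.columns, "sodium_mg" in frame.columns
    if has_g == has_mg:
        raise SchemaError("composition table must have exactly one of 'sodium_g' or 'sodium_mg'")

    records: list[IngredientRecord] = []
    seen: dict[str, int] = {}
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2  # 1-based data row accounting for the header line
        rid = str(row["id"])
        if rid in seen:
            raise DuplicateIdError(f"row {rowno}: duplicate id {rid!r} (first seen at row {seen[rid]})")
        seen[rid] = rowno
        sodium = float(row["sodium_g"]) if has_g else float(row["sodium_mg"]) / 1000.0

        def _opt(col: str) -> float | None:
            value = row[col]
            return None if pd.isna(value) else float(value)

        nv = NutrientVector(
            fat=float(row["fat_g"]),
            protein=float(row["protein_g"]),
            carbohydrate=float(row["carbohydrate_g"]),
            sodium=sodium,
            water=_opt("water_g"),
            ash=_opt("ash_g"),
        )
        try:
            record = IngredientRecord(
                id=rid,
                name=str(row["name"]),
                general_category=str(row["general_category"]).strip(),
                subclass=str(row["subclass"]).strip(),
                edible_fraction=float(row["edible_fraction"]),
                nutrients=nv,
            ).validate()
        except RecordValidationError as exc:
            raise RecordValidationError(f"row {rowno}: {exc}") from exc
        records.append(record)
    return records


def records_to_frame(records: Sequence[IngredientRecord]) -> pd.DataFrame:
    """Inverse of :func:`read_composition_table` (sodium written in grams)."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "name": r.name, "general_category": r.general_category,
            "subclass": r.subclass, "edible_fraction": r.edible_fraction,
            "water_g": r.nutrients.water, "protein_g": r.nutrients.protein,
            "fat_g": r.nutrients.fat, "carbohydrate_g": r.nutrients.carbohydrate,
            "ash_g": r.nutrients.ash, "sodium_g": r.nutrients.sodium,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Representative values
# ---------------------------------------------------------------------------

def representative_values(
    records: Sequence[IngredientRecord],
    level: Literal["subclass", "general_category"] = "subclass",
) -> list[CategoryRepresentative]:
    """Unweighted arithmetic-mean nutrient content per group.

    Grouping is by ``subclass`` (default) or ``general_category``.  A
    nutrient missing on some members (optional water/ash) is averaged over
    the members that carry it, and the per-nutrient count is reported.
    """
    if not records:
        raise DomainError("representative_values requires at least one record")
    if level not in ("subclass", "general_category"):
        raise DomainError(f"unknown grouping level {level!r}")

    groups: dict[tuple[str, str | None], list[IngredientRecord]] = {}
    for record in records:
        if level == "subclass":
            key = (record.general_category, record.subclass)
        else:
            key = (record.general_category, None)
        groups.setdefault(key, []).append(record)

    representatives = []
    for (category, subclass), members in groups.items():
        means: dict[str, float | None] = {}
        counts: dict[str, int] = {}
        for name in MODELED_NUTRIENTS + OPTIONAL_NUTRIENTS:
            values = [getattr(m.nutrients, name) for m in members if getattr(m.nutrients, name) is not None]
            counts[name] = len(values)
            means[name] = (sum(values) / len(values)) if values else None
        nv = NutrientVector(
            fat=means["fat"], protein=means["protein"],  # type: ignore[arg-type]
            carbohydrate=means["carbohydrate"], sodium=means["sodium"],  # type: ignore[arg-type]
            water=means["water"], ash=means["ash"],
        )
        representatives.append(CategoryRepresentative(
            general_category=category, subclass=subclass,
            nutrients=nv, n_members=len(members), n_per_nutrient=counts,
        ))
    return representatives


def representatives_to_frame(reps: Sequence[CategoryRepresentative]) -> pd.DataFrame:
    rows = []
    for r in reps:
        rows.append({
            "general_category": r.general_category, "subclass": r.subclass,
            "water_g": r.nutrients.water, "protein_g": r.nutrients.protein,
            "fat_g": r.nutrients.fat, "carbohydrate_g": r.nutrients.carbohydrate,
            "ash_g": r.nutrients.ash, "sodium_g": r.nutrients.sodium,
            "n_members": r.n_members,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResolvedIngredient:
    """Result of resolving a recipe ingredient against the database."""

    nutrients: NutrientVector
    level: Literal["exact", "subclass", "category"]
    general_category: str
    subclass: str | None
    edible_fraction: float | None  # None when resolved to a representative
    matched: str  # id/name or group key that supplied the values


def _norm(label: str | None) -> str | None:
    return label.strip().casefold() if label else None


class CompositionDB:
    """Composition records plus precomputed subclass and category representatives."""

    def __init__(self, records: Sequence[IngredientRecord]):
        if not records:
            raise DomainError("CompositionDB requires at least one record")
        self.records = list(records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate ids in composition records")
        self._by_id = {r.id: r for r in self.records}
        self._by_name: dict[str, IngredientRecord] = {}
        for r in self.records:
            self._by_name.setdefault(_norm(r.name), r)  # first wins on name collision
        self.subclass_representatives = representative_values(self.records, "subclass")
        self.category_representatives = representative_values(self.records, "general_category")
        self._rep_by_subclass = {_norm(r.subclass): r for r in self.subclass_representatives}
        self._rep_by_category = {_norm(r.general_category): r for r in self.category_representatives}

    @classmethod
    def from_csv(cls, source: str | Path | pd.DataFrame) -> "CompositionDB":
        return cls(read_composition_table(source))

    def known_subclasses(self) -> list[str]:
        return sorted({r.subclass for r in self.records})

    def resolve(
        self,
        query_name: str,
        subclass: str | None = None,
        general_category: str | None = None,
    ) -> ResolvedIngredient:
        """Resolve an ingredient name to nutrient values.

        Exact id/name matches return the record's own values.  Otherwise a
        declared subclass (then general category) falls back to the group's
        representative mean — the mechanism by which unknown varieties of a
        known food type are priced in.  Representatives are returned exactly
        as stored; nothing is interpolated.
        """
        record = self._by_id.get(query_name) or self._by_name.get(_norm(query_name))
        if record is not None:
            return ResolvedIngredient(record.nutrients, "exact", record.general_category,
                                      record.subclass, record.edible_fraction, record.id)
        rep = self._rep_by_subclass.get(_norm(subclass))
        if rep is not None:
            return ResolvedIngredient(rep.nutrients, "subclass", rep.general_category,
                                      rep.subclass, None, f"{rep.general_category}/{rep.subclass}")
        rep = self._rep_by_category.get(_norm(general_category))
        if rep is not None:
            return ResolvedIngredient(rep.nutrients, "category", rep.general_category,
                                      None, None, rep.general_category)
        pool = self.known_subclasses()
        near = difflib.get_close_matches(subclass or query_name, pool, n=3, cutoff=0.4)
        raise UnresolvableIngredientError(query_name, near or pool[:3])


# ---------------------------------------------------------------------------
# Carbohydrate by difference
# ---------------------------------------------------------------------------

def carbohydrate_by_difference(total_mass: float, water: float, ash: float,
                               protein: float, fat: float) -> float:
    """Carbohydrate as the proximate remainder: total - water - ash - protein - fat.

    A deficit of up to 0.5 g (components slightly exceeding the total) is
    treated as measurement noise and clamped to 0 with a logged diagnostic;
    a larger deficit raises :class:`InconsistentProximatesError`.
    """
    for name, value in (("total_mass", total_mass), ("water", water), ("ash", ash),
                        ("protein", protein), ("fat", fat)):
        if not math.isfinite(value) or value < 0:
            raise DomainError(f"{name} must be finite and >= 0, got {value!r}")
    result = total_mass - water - ash - protein - fat
    if result >= 0:
        return result
    if result >= -PROXIMATE_TOLERANCE_G:
        logger.warning(
            "carbohydrate by difference gave %.4f g (components sum %.4f g over total %.4f g); clamped to 0",
            result, water + ash + protein + fat, total_mass,
        )
        return 0.0
    raise InconsistentProximatesError(
        f"components sum to {water + ash + protein + fat:.4f} g, exceeding total mass "
        f"{total_mass:.4f} g by more than {PROXIMATE_TOLERANCE_G} g"
    )
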