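"""Cooking-method correction factors from paired calculated/detected data.

For every dish and nutrient the ratio calculated/detected is formed; a
ratio <= 0.5 or >= 2 (inclusive, evaluated on the unrounded value) marks a
cell where the uncorrected model misses the laboratory value badly.  For
each (food category, cooking method, nutrient) key with at least one
flagged cell, a multiplicative correction factor is derived as the mean
(or median) of detected/calculated over the key's cells, so that
factor x calculated re-centres the model on the detected values.
Validation reports mean absolute error and mean absolute percentage error
before and after applying the factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from statistics import mean, median
from typing import Iterable, Literal, Sequence

import pandas as pd

from .composition import MODELED_NUTRIENTS, NutrientVector
from .cooking import CookingMethod, _key_variants, _norm_key
from .errors import AlignmentError, ConfigError, DomainError, SchemaError

logger = logging.getLogger(__name__)

SCREEN_LOW = 0.5
SCREEN_HIGH = 2.0


@dataclass(frozen=True)
class PairedObservation:
    """One dish with model-calculated and laboratory-detected per-100 g values."""

    dish_name: str
    category: str
    method: CookingMethod
    calculated: NutrientVector
    detected: NutrientVector

    def __post_init__(self) -> None:
        for name in MODELED_NUTRIENTS:
            if getattr(self.detected, name) < 0 or getattr(self.calculated, name) < 0:
                raise DomainError(f"{self.dish_name!r}: negative {name} in paired observation")


@dataclass(frozen=True)
class RatioCell:
    """One calculated/detected ratio, as screened and as printed."""

    dish_name: str
    category: str
    method: CookingMethod
    nutrient: str
    ratio: float | None          # unrounded; None when detected = 0 with calculated > 0
    display: float | None        # half-up rounded for printing
    flagged: bool

    @property
    def display_str(self) -> str:
        if self.display is None:
            return "undefined*"
        text = f"{self.display:.2f}"
        return text + "*" if self.flagged else text


def round_half_up(value: float, dp: int = 2) -> float:
    """Decimal half-up rounding (2.005 -> 2.01), matching print conventions."""
    quantum = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def screen(ratio: float | None, low: float = SCREEN_LOW, high: float = SCREEN_HIGH) -> bool:
    """True when a calculated/detected ratio marks a badly-missed cell.

    Bounds are inclusive; an undefined ratio (detected 0, calculated > 0)
    always flags.
    """
    if ratio is None:
        return True
    if ratio < 0:
        raise DomainError(f"ratio must be >= 0, got {ratio!r}")
    return ratio <= low or ratio >= high


def ratio_table(
    pairs: Sequence[PairedObservation],
    round_dp: int = 2,
    low: float = SCREEN_LOW,
    high: float = SCREEN_HIGH,
) -> list[RatioCell]:
    """Per-cell calculated/detected ratios with screening flags.

    Flags are computed on the unrounded ratio; ``display`` is half-up
    rounded to ``round_dp``.  A calculated value of exactly 0 gives ratio 0
    (flagged); detected 0 with calculated > 0 gives an undefined, flagged
    cell.
    """
    cells: list[RatioCell] = []
    for pair in pairs:
        for nutrient in MODELED_NUTRIENTS:
            calc = getattr(pair.calculated, nutrient)
            det = getattr(pair.detected, nutrient)
            if calc == 0:
                ratio: float | None = 0.0
            elif det == 0:
                ratio = None
            else:
                ratio = calc / det
            cells.append(RatioCell(
                dish_name=pair.dish_name, category=pair.category, method=pair.method,
                nutrient=nutrient, ratio=ratio,
                display=None if ratio is None else round_half_up(ratio, round_dp),
                flagged=screen(ratio, low, high),
            ))
    return cells


def ratio_cells_to_frame(cells: Sequence[RatioCell]) -> pd.DataFrame:
    return pd.DataFrame([
        {"dish_name": c.dish_name, "category": c.category, "method": c.method.value,
         "nutrient": c.nutrient, "ratio": c.display, "flagged": c.flagged,
         "display": c.display_str}
        for c in cells
    ])


# ---------------------------------------------------------------------------
# Building pairs from tables
# ---------------------------------------------------------------------------

_WIDE_COLUMNS = ("category", "dish_name", "method")


def align_wide_tables(calculated: pd.DataFrame, detected: pd.DataFrame) -> list[PairedObservation]:
    """Pair two wide tables (one row per dish, one column per nutrient).

    Alignment is by row position within the shared category sequence; dish
    labels are taken from the calculated table.  The detected table may
    carry ``<nutrient>_mean`` columns (means of replicate analyses).
    Mismatched row counts or category block structure raise
    :class:`AlignmentError` listing the orphaned rows.
    """
    for frame, which in ((calculated, "calculated"), (detected, "detected")):
        missing = [c for c in _WIDE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"{which} table is missing columns: {', '.join(missing)}")
    if len(calculated) != len(detected):
        longer, shorter = (calculated, detected) if len(calculated) > len(detected) else (detected, calculated)
        orphans = longer["dish_name"].iloc[len(shorter):].tolist()
        raise AlignmentError(
            f"tables have {len(calculated)} vs {len(detected)} rows; unmatched dishes: {orphans}"
        )
    calc_blocks = [len(g) for _, g in calculated.groupby((calculated["category"] != calculated["category"].shift()).cumsum())]
    det_blocks = [len(g) for _, g in detected.groupby((detected["category"] != detected["category"].shift()).cumsum())]
    if calc_blocks != det_blocks:
        raise AlignmentError(
            f"category block structure differs between tables: {calc_blocks} vs {det_blocks}"
        )

    def _value(frame: pd.DataFrame, i: int, nutrient: str) -> float:
        col = nutrient if nutrient in frame.columns else f"{nutrient}_mean"
        if col not in frame.columns:
            raise SchemaError(f"table lacks a {nutrient!r} or {nutrient}_mean column")
        return float(frame.iloc[i][col])

    pairs = []
    for i in range(len(calculated)):
        row = calculated.iloc[i]
        pairs.append(PairedObservation(
            dish_name=str(row["dish_name"]),
            category=str(row["category"]),
            method=CookingMethod.parse(row["method"]),
            calculated=NutrientVector(**{n: _value(calculated, i, n) for n in MODELED_NUTRIENTS}),
            detected=NutrientVector(**{n: _value(detected, i, n) for n in MODELED_NUTRIENTS}),
        ))
    return pairs


def pairs_from_long(frame: pd.DataFrame) -> list[PairedObservation]:
    """Build pairs from a long table: dish_name,category,method,nutrient,calculated,detected."""
    needed = {"dish_name", "category", "method", "nutrient", "calculated", "detected"}
    if not needed.issubset(frame.columns):
        raise SchemaError(f"long-form table needs columns {sorted(needed)}")
    pairs = []
    for (dish, category, method), group in frame.groupby(["dish_name", "category", "method"], sort=False):
        values = {str(r["nutrient"]): (float(r["calculated"]), float(r["detected"])) for _, r in group.iterrows()}
        missing = set(MODELED_NUTRIENTS) - set(values)
        if missing:
            raise AlignmentError(f"dish {dish!r} lacks nutrients: {sorted(missing)}")
        pairs.append(PairedObservation(
            dish_name=str(dish), category=str(category), method=CookingMethod.parse(method),
            calculated=NutrientVector(**{n: values[n][0] for n in MODELED_NUTRIENTS}),
            detected=NutrientVector(**{n: values[n][1] for n in MODELED_NUTRIENTS}),
        ))
    return pairs


# ---------------------------------------------------------------------------
# Factor derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionFactor:
    category: str
    method: CookingMethod
    nutrient: str
    factor: float
    n_support: int
    active: bool

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise DomainError(f"correction factor must be > 0, got {self.factor!r}")


def derive_factors(
    pairs: Sequence[PairedObservation],
    low: float = SCREEN_LOW,
    high: float = SCREEN_HIGH,
    aggregation: Literal["mean", "median"] = "mean",
) -> list[CorrectionFactor]:
    """Derive correction factors per (category, method, nutrient) key.

    A key becomes *active* when at least one of its cells is flagged by the
    screening rule; its factor is then the aggregate of detected/calculated
    over the key's cells with calculated > 0 (cells where that quotient is
    undefined are excluded and logged).  Unflagged keys keep factor 1.0,
    inactive.  A flagged key whose every cell is undefined cannot be
    derived: factor 1.0 with a warning.
    """
    if aggregation not in ("mean", "median"):
        raise ConfigError(f"aggregation must be 'mean' or 'median', got {aggregation!r}")
    aggregate = mean if aggregation == "mean" else median

    grouped: dict[tuple[str, CookingMethod, str], dict] = {}
    for pair in pairs:
        for nutrient in MODELED_NUTRIENTS:
            calc = getattr(pair.calculated, nutrient)
            det = getattr(pair.detected, nutrient)
            if calc == 0:
                ratio: float | None = 0.0
            elif det == 0:
                ratio = None
            else:
                ratio = calc / det
            key = (pair.category, pair.method, nutrient)
            slot = grouped.setdefault(key, {"contrib": [], "flagged": False, "excluded": 0})
            slot["flagged"] = slot["flagged"] or screen(ratio, low, high)
            if calc > 0:
                slot["contrib"].append(det / calc)
            else:
                slot["excluded"] += 1

    factors = []
    for (category, method, nutrient), slot in grouped.items():
        contrib: list[float] = slot["contrib"]  # type: ignore[assignment]
        if slot["excluded"]:
            logger.info("key (%s, %s, %s): %d cell(s) with calculated = 0 excluded from aggregation",
                        category, method.value, nutrient, slot["excluded"])
        if not slot["flagged"]:
            factors.append(CorrectionFactor(category, method, nutrient, 1.0,
                                            n_support=len(contrib), active=False))
            continue
        if not contrib or aggregate(contrib) <= 0:
            logger.warning("key (%s, %s, %s) is flagged but underivable; keeping factor 1.0",
                           category, method.value, nutrient)
            factors.append(CorrectionFactor(category, method, nutrient, 1.0,
                                            n_support=0, active=False))
            continue
        factors.append(CorrectionFactor(category, method, nutrient, float(aggregate(contrib)),
                                        n_support=len(contrib), active=True))
    return factors


class CorrectionDB:
    """Lookup wrapper over derived correction factors (inactive keys give 1.0)."""

    def __init__(self, factors: Iterable[CorrectionFactor]):
        self.factors = list(factors)
        self._index: dict[tuple[str, CookingMethod, str], CorrectionFactor] = {
            (_norm_key(f.category), f.method, f.nutrient): f for f in self.factors
        }

    def get(self, category: str, method: "str | CookingMethod", nutrient: str) -> float:
        method = CookingMethod.parse(method)
        for variant in _key_variants(category):
            hit = self._index.get((variant, method, nutrient))
            if hit is not None:
                return hit.factor if hit.active else 1.0
        return 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"category": f.category, "method": f.method.value, "nutrient": f.nutrient,
             "factor": f.factor, "n_support": f.n_support, "active": f.active}
            for f in self.factors
        ])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CorrectionDB":
        needed = {"category", "method", "nutrient", "factor", "n_support", "active"}
        if not needed.issubset(frame.columns):
            raise SchemaError(f"correction-factor table needs columns {sorted(needed)}")
        return cls(
            CorrectionFactor(
                category=str(r["category"]), method=CookingMethod.parse(r["method"]),
                nutrient=str(r["nutrient"]), factor=float(r["factor"]),
                n_support=int(r["n_support"]),
                active=str(r["active"]).strip().lower() in ("true", "1"),
            )
            for _, r in frame.iterrows()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrectionDB":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Before/after validation
# ---------------------------------------------------------------------------

def validate_correction(
    pairs: Sequence[PairedObservation],
    factors: "CorrectionDB | Sequence[CorrectionFactor]",
) -> dict:
    """Compare calculated vs detected values before and after correction.

    Returns, per nutrient and overall, the mean absolute error (g/100 g)
    and mean absolute percentage error (over cells with detected > 0),
    before and after multiplying each calculated value by its applicable
    factor, plus a flag for any nutrient whose error increased.
    """
    db = factors if isinstance(factors, CorrectionDB) else CorrectionDB(factors)
    errors: dict[str, dict[str, list[float]]] = {
        n: {"ae_before": [], "ae_after": [], "ape_before": [], "ape_after": []}
        for n in MODELED_NUTRIENTS
    }
    for pair in pairs:
        for nutrient in MODELED_NUTRIENTS:
            calc = getattr(pair.calculated, nutrient)
            det = getattr(pair.detected, nutrient)
            corrected = calc * db.get(pair.category, pair.method, nutrient)
            slot = errors[nutrient]
            slot["ae_before"].append(abs(calc - det))
            slot["ae_after"].append(abs(corrected - det))
            if det > 0:
                slot["ape_before"].append(abs(calc - det) / det * 100.0)
                slot["ape_after"].append(abs(corrected - det) / det * 100.0)

    def _summary(slot: dict[str, list[float]]) -> dict:
        return {
            "mae_before": mean(slot["ae_before"]) if slot["ae_before"] else math.nan,
            "mae_after": mean(slot["ae_after"]) if slot["ae_after"] else math.nan,
            "mape_before": mean(slot["ape_before"]) if slot["ape_before"] else math.nan,
            "mape_after": mean(slot["ape_after"]) if slot["ape_after"] else math.nan,
        }

    report: dict = {"per_nutrient": {}, "n_dishes": len(pairs)}
    pooled = {k: [] for k in ("ae_before", "ae_after", "ape_before", "ape_after")}
    for nutrient, slot in errors.items():
        entry = _summary(slot)
        entry["error_increased"] = (
            not math.isnan(entry["mape_after"]) and entry["mape_after"] > entry["mape_before"]
        ) or entry["mae_after"] > entry["mae_before"]
        report["per_nutrient"][nutrient] = entry
        for k in pooled:
            pooled[k].extend(slot[k])
    report["overall"] = _summary(pooled)
    report["overall"]["error_increased"] = report["overall"]["mae_after"] > report["overall"]["mae_before"]
    return report
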