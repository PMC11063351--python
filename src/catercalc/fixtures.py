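"""Packaged reference tables.

The distribution ships five plain-CSV tables transcribed from a published
cooking study of common Chinese catering dishes: the sampling plan, the
raw-to-cooked yield ratios of 44 dishes, laboratory-detected macronutrient
values (mean and SD of replicates) for 48 dishes, the corresponding
model-calculated values, and the printed calculated/detected ratio table
with its screening marks.  The detected/calculated tables drive
correction-factor derivation; the printed ratio table serves as the
reference the computed one is checked against.

Known label drift between the source tables (a fish category printed as
"Scallops" in the detected table but "Hairtail" in the calculated one;
method labels differing for two dishes) is preserved verbatim; pairing is
by row position, which the category block structure supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .cooking import RatioDB
from .correction import PairedObservation, align_wide_tables
from .errors import FixtureIntegrityError

_EXPECTED_ROWS = {
    "raw_cooked_ratios.csv": 44,
    "detected_nutrients.csv": 48,
    "calculated_nutrients.csv": 48,
    "printed_ratio_table.csv": 48,
    "sampling_plan.csv": 15,
}


@dataclass(frozen=True)
class FixtureBundle:
    ratio_table: pd.DataFrame
    detected_table: pd.DataFrame
    calculated_table: pd.DataFrame
    printed_ratio_table: pd.DataFrame
    sampling_plan: pd.DataFrame


def _read(name: str) -> pd.DataFrame:
    path = resources.files("catercalc").joinpath("data", name)
    with resources.as_file(path) as real:
        frame = pd.read_csv(real)
    expected = _EXPECTED_ROWS[name]
    if len(frame) != expected:
        raise FixtureIntegrityError(f"{name}: expected {expected} rows, found {len(frame)}")
    return frame


def _blocks(frame: pd.DataFrame) -> list[int]:
    change = (frame["category"] != frame["category"].shift()).cumsum()
    return [len(g) for _, g in frame.groupby(change)]


def load_fixtures() -> FixtureBundle:
    """Load and integrity-check the packaged tables."""
    bundle = FixtureBundle(
        ratio_table=_read("raw_cooked_ratios.csv"),
        detected_table=_read("detected_nutrients.csv"),
        calculated_table=_read("calculated_nutrients.csv"),
        printed_ratio_table=_read("printed_ratio_table.csv"),
        sampling_plan=_read("sampling_plan.csv"),
    )
    if not (bundle.ratio_table["ratio"] > 0).all():
        raise FixtureIntegrityError("ratio table contains non-positive ratios")
    if not (_blocks(bundle.detected_table) == _blocks(bundle.calculated_table)
            == _blocks(bundle.printed_ratio_table)):
        raise FixtureIntegrityError("category block structure differs across paired tables")
    return bundle


def fixture_ratio_db(bundle: FixtureBundle | None = None) -> RatioDB:
    """The packaged raw-to-cooked ratio database."""
    bundle = bundle or load_fixtures()
    return RatioDB.from_frame(bundle.ratio_table)


def fixture_pairs(bundle: FixtureBundle | None = None) -> list[PairedObservation]:
    """Paired calculated/detected observations from the packaged tables."""
    bundle = bundle or load_fixtures()
    return align_wide_tables(bundle.calculated_table, bundle.detected_table)
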