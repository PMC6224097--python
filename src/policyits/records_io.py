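"""Birth-record table I/O, sample-flow accounting and the characteristics ledger.

The on-disk format is a UTF-8 CSV/TSV with a header row and one row per
live birth.  ``birth_month`` is an integer month index with 0 = January
2000; binary columns are 0/1.  The optional ``true_exposed`` column carries
generator truth and is preserved when present.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import AGE_LEVELS, EDUCATION_LEVELS, INTERVAL_LEVELS, ORDER_LEVELS
from .scenarios import ExposureScenario

COLUMNS = [
    "region_id", "cluster_id", "household_id", "woman_id", "birth_id",
    "birth_month", "calendar_month_of_year", "facility_delivery",
    "neonatal_death", "rural", "wealth_quintile", "education", "literate",
    "mother_age_group", "multiple_birth", "birth_order_cat",
    "preceding_interval_cat", "mother_worked", "newborn_female",
]
OPTIONAL_COLUMNS = ["true_exposed"]

_BINARY = ["facility_delivery", "neonatal_death", "rural", "literate",
           "multiple_birth", "mother_worked", "newborn_female"]
_CATEGORICAL = {
    "education": EDUCATION_LEVELS,
    "mother_age_group": AGE_LEVELS,
    "birth_order_cat": ORDER_LEVELS,
    "preceding_interval_cat": INTERVAL_LEVELS,
}


def write_records(records: pd.DataFrame, path, dialect: str = "csv") -> None:
    """Write the record table as CSV (default) or TSV."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    cols = COLUMNS + [c for c in OPTIONAL_COLUMNS if c in records.columns]
    records.loc[:, cols].to_csv(path, sep=sep, index=False)


def read_records(path, dialect: str = "csv") -> pd.DataFrame:
    """Read and validate a birth-record table.

    Raises ``ValueError`` naming the offending column (and row, for bad
    category labels) on contract violations.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    unknown = [c for c in df.columns
               if c not in COLUMNS and c not in OPTIONAL_COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s): {unknown}")
    for col, levels in _CATEGORICAL.items():
        vals = df[col].astype(str)
        bad = ~vals.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown category label {vals.iloc[row]!r} in column "
                f"{col!r} at row {row}")
        df[col] = vals
    for col in _BINARY + ["true_exposed"] * ("true_exposed" in df.columns):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            raise ValueError(f"column {col!r} must be 0/1")
        df[col] = df[col].astype(int)
    for col in ("region_id", "cluster_id", "household_id", "woman_id",
                "birth_id", "birth_month", "calendar_month_of_year",
                "wealth_quintile"):
        df[col] = df[col].astype(int)
    if not df["wealth_quintile"].isin(range(1, 6)).all():
        raise ValueError("column 'wealth_quintile' must be in 1..5")
    return df


def validate_nesting(records: pd.DataFrame) -> None:
    """Check strict nesting birth < woman < household < cluster < region."""
    for child, parent in (("woman_id", "household_id"),
                          ("household_id", "cluster_id"),
                          ("cluster_id", "region_id")):
        n_parents = records.groupby(child)[parent].nunique()
        if (n_parents > 1).any():
            bad = n_parents[n_parents > 1].index[0]
            raise ValueError(f"{child}={bad} maps to multiple {parent} values")


# ---------------------------------------------------------------------------
# flow accounting (sample-selection diagram)
# ---------------------------------------------------------------------------

@dataclass
class FlowCounts:
    households_selected: int
    households_surveyed: int
    women_identified: int
    women_responding: int
    births_10yr: int
    births_5yr: int
    deliveries_5yr: int
    women_in_analysis: int
    households_in_analysis: int
    excluded_by_scenario: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def collapse_deliveries(records: pd.DataFrame) -> pd.DataFrame:
    """One row per delivery: multiple births of a woman in the same month
    collapse to a single record (the first)."""
    return records.drop_duplicates(subset=["woman_id", "birth_month"],
                                   keep="first")


def flow_accounting(records: pd.DataFrame, survey_month: int,
                    scenario: Optional[ExposureScenario] = None,
                    window_5yr: int = 60, window_10yr: int = 120
                    ) -> FlowCounts:
    """Reproduce the sample-selection flow for a record table.

    Window membership is ``survey_month - window <= birth_month <
    survey_month``.  The survey frame counts (households/women selected and
    responding) are taken from the table itself -- the synthetic survey has
    full response.
    """
    if len(records) and survey_month < records["birth_month"].max():
        raise ValueError("survey_month must be >= every birth_month")
    if len(records) == 0:
        return FlowCounts(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
    bm = records["birth_month"]
    in10 = records[(bm >= survey_month - window_10yr) & (bm < survey_month)]
    in5 = records[(bm >= survey_month - window_5yr) & (bm < survey_month)]
    excluded = 0
    if scenario is not None and scenario.exclusion_window is not None:
        excluded = int(scenario.excluded(in10["birth_month"].to_numpy()).sum())
    n_hh = records["household_id"].nunique()
    n_women = records["woman_id"].nunique()
    return FlowCounts(
        households_selected=n_hh, households_surveyed=n_hh,
        women_identified=n_women, women_responding=n_women,
        births_10yr=len(in10), births_5yr=len(in5),
        deliveries_5yr=len(collapse_deliveries(in5)),
        women_in_analysis=in10["woman_id"].nunique(),
        households_in_analysis=in10["household_id"].nunique(),
        excluded_by_scenario=excluded)


# ---------------------------------------------------------------------------
# characteristics ledger (descriptive table by period)
# ---------------------------------------------------------------------------

def round_percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage 100*count/total, rounded half-up to `ndigits` decimals."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


_LEDGER_ROWS = [
    ("neonatal_death", "Neonatal deaths", {1: None}),
    ("newborn_female", "New-born's sex (male)", {0: None}),
    ("multiple_birth", "Number of births (multiple)", {1: None}),
    ("mother_age_group", "Woman's age (years)", AGE_LEVELS),
    ("preceding_interval_cat", "Previous birth interval", INTERVAL_LEVELS),
    ("literate", "Woman's literacy (illiterate)", {0: None}),
    ("education", "Woman's education", EDUCATION_LEVELS),
    ("mother_worked", "Woman's occupation (worked)", {1: None}),
    ("wealth_quintile", "Household wealth", (1, 2, 3, 4, 5)),
    ("rural", "Place of residence (rural)", {1: None}),
]


@dataclass
class CharacteristicsTable:
    """Counts and one-decimal percentages per covariate category and period."""

    table: Dict[str, Dict[str, Dict[str, object]]]
    totals: Dict[str, int]
    excluded: int

    def to_json(self) -> str:
        return json.dumps({"totals": self.totals, "excluded": self.excluded,
                           "table": self.table}, indent=2)

    def to_text(self) -> str:
        lines = [f"{'Characteristic':<42}"
                 f"{'Pre n=' + str(self.totals['pre']):>18}"
                 f"{'Post n=' + str(self.totals['post']):>18}"
                 f"{'Total n=' + str(self.totals['total']):>18}"]
        for cov, cats in self.table.items():
            lines.append(cov)
            for cat, cell in cats.items():
                row = f"  {cat:<40}"
                for period in ("pre", "post", "total"):
                    c, p = cell[period]
                    row += f"{c:>10,} ({p:>4.1f})"
                lines.append(row)
        if self.excluded:
            lines.append(f"Excluded by scenario: {self.excluded}")
        return "\n".join(lines)


def characteristics_table(records: pd.DataFrame,
                          scenario: ExposureScenario) -> CharacteristicsTable:
    """Descriptive counts and percentages by pre/post period.

    The period split follows the scenario cutoff; births the scenario
    excludes are dropped from both periods and reported separately.
    """
    bm = records["birth_month"].to_numpy()
    excl = scenario.excluded(bm)
    kept = records.loc[~excl]
    post = scenario.exposed(kept["birth_month"].to_numpy()).astype(bool)
    periods = {"pre": kept.loc[~post], "post": kept.loc[post], "total": kept}
    totals = {k: len(v) for k, v in periods.items()}

    table: Dict[str, Dict[str, Dict[str, object]]] = {}
    for col, label, cats in _LEDGER_ROWS:
        if isinstance(cats, dict):  # single summarized binary level
            level = next(iter(cats))
            rows = {label: {p: (int((periods[p][col] == level).sum()),
                                round_percent(
                                    int((periods[p][col] == level).sum()),
                                    totals[p]))
                            for p in periods}}
        else:
            rows = {}
            for cat in cats:
                rows[str(cat)] = {
                    p: (int((periods[p][col] == cat).sum()),
                        round_percent(int((periods[p][col] == cat).sum()),
                                      totals[p]))
                    for p in periods}
        table[label] = rows
    return CharacteristicsTable(table=table, totals=totals,
                                excluded=int(excl.sum()))
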