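"""Exposure-definition scenarios for the policy cutoff.

Calendar time is an integer month index with 0 = January 2000, so the
official policy start (1 January 2007) is month 84.  Because births are
dated to the month, a birth in the cutoff month itself is treated as
exposed.  Three scenarios are supported:

``primary``
    Exposure starts at the official date (January 2007).
``shift_april``
    Exposure starts in April 2007, the latest district roll-out date; births
    in January-March 2007 are coded unexposed.
``exclude_q1``
    The official cutoff is kept but births in January-March 2007, whose
    exposure cannot be determined, are dropped from the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

JAN_2000 = 0
JAN_2007 = 84
APR_2007 = 87
MAR_2007 = 86
JUN_2005 = 65


def month_index(year: int, month: int) -> int:
    """Month index (0 = January 2000) for a calendar year/month."""
    return (year - 2000) * 12 + (month - 1)


@dataclass(frozen=True)
class ExposureScenario:
    """A rule assigning exposure status (and possible exclusion) by birth month."""

    name: str
    cutoff_month: int
    exclusion_window: Optional[Tuple[int, int]] = None  # inclusive [start, end]

    @classmethod
    def primary(cls) -> "ExposureScenario":
        return cls("primary", JAN_2007)

    @classmethod
    def shift_april(cls) -> "ExposureScenario":
        return cls("shift_april", APR_2007)

    @classmethod
    def exclude_q1(cls) -> "ExposureScenario":
        return cls("exclude_q1", JAN_2007, (JAN_2007, MAR_2007))

    @classmethod
    def from_name(cls, name: str) -> "ExposureScenario":
        try:
            return {"primary": cls.primary,
                    "shift_april": cls.shift_april,
                    "exclude_q1": cls.exclude_q1}[name]()
        except KeyError:
            raise ValueError(f"unknown scenario name: {name!r}") from None

    def exposed(self, birth_month: np.ndarray) -> np.ndarray:
        """0/1 exposure indicator: exposed iff birth_month >= cutoff."""
        return (np.asarray(birth_month) >= self.cutoff_month).astype(int)

    def excluded(self, birth_month: np.ndarray) -> np.ndarray:
        """Boolean mask of births falling in the exclusion window."""
        bm = np.asarray(birth_month)
        if self.exclusion_window is None:
            return np.zeros(bm.shape, dtype=bool)
        lo, hi = self.exclusion_window
        return (bm >= lo) & (bm <= hi)

    def post_time(self, birth_month: np.ndarray) -> np.ndarray:
        """Months since the cutoff, 0 before it."""
        return np.maximum(0, np.asarray(birth_month) - self.cutoff_month)


def apply_scenario(records: pd.DataFrame, scenario: ExposureScenario):
    """Assign exposure under a scenario and drop excluded births.

    Returns ``(included, n_excluded)`` where ``included`` is a copy of the
    record table restricted to determinable births with an added integer
    ``exposed`` column.
    """
    bm = records["birth_month"].to_numpy()
    keep = ~scenario.excluded(bm)
    out = records.loc[keep].copy()
    out["exposed"] = scenario.exposed(out["birth_month"].to_numpy())
    return out, int((~keep).sum())
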