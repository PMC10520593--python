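"""Cohort data model and delimited-text I/O.

A cohort is one row per participant: an id, a group label, a site, basic
demographics (age, sex) and one raw score column per battery test.  Missing
scores are explicit (``NaN`` in memory; empty cell or ``NA`` on disk) and
are never silently imputed — every downstream summary reports the
denominator it was computed on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import BatterySpec
from .errors import ConfigurationError, ValidationError

#: Mandatory non-score columns, in file order.
ID_COLUMNS = ("participant_id", "group", "site", "age", "sex")

#: Cell contents accepted as missing on read; missing is written as "".
MISSING_TOKENS = ("", "NA")


@dataclass
class CohortTable:
    """Participant-level table bound to a battery.

    ``data`` holds one row per participant with columns
    ``participant_id, group, site, age, sex`` followed by one float column
    per battery test (``NaN`` = missing).
    """

    data: pd.DataFrame
    battery: BatterySpec

    def __post_init__(self) -> None:
        missing_cols = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ConfigurationError(f"cohort is missing mandatory column(s): {missing_cols}")
        missing_tests = [t for t in self.battery.names if t not in self.data.columns]
        if missing_tests:
            raise ConfigurationError(f"cohort is missing score column(s): {missing_tests}")
        ids = self.data["participant_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate participant_id values: {dupes[:5]}")
        # canonical column order; score columns as float with NaN for missing
        cols = list(ID_COLUMNS) + self.battery.names
        df = self.data.loc[:, cols].reset_index(drop=True).copy()
        for t in self.battery.names:
            df[t] = pd.to_numeric(df[t], errors="raise").astype(float)
        df["participant_id"] = df["participant_id"].astype(str)
        df["group"] = df["group"].astype(str)
        df["site"] = df["site"].astype(str)
        self.data = df

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    @property
    def scores(self) -> pd.DataFrame:
        """Score block indexed by participant_id, columns in battery order."""
        return self.data.set_index("participant_id")[self.battery.names]

    def require_group(self, label: str) -> None:
        if (self.data["group"] == label).sum() == 0:
            raise ValidationError(f"no participant carries the group label {label!r}")


@dataclass
class CompletenessSummary:
    """Per-test missingness and the complete-case count."""

    missing_fraction: pd.Series  # index: test name, values in [0, 1]
    complete_cases: int
    n: int
    missing_count: pd.Series = field(repr=False, default=None)


def read_cohort(
    path: str | Path,
    battery: BatterySpec,
    *,
    delimiter: str = ",",
    missing_tokens: tuple[str, ...] = MISSING_TOKENS,
) -> CohortTable:
    """Read a cohort CSV.

    Empty cells and ``NA`` in score columns become missing; any other
    non-numeric score cell is an error naming its row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in ID_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: header is missing mandatory column(s): {missing_cols}"
        )
    missing_tests = [t for t in battery.names if t not in raw.columns]
    if missing_tests:
        raise ConfigurationError(f"{path}: header is missing score column(s): {missing_tests}")

    for t in battery.names:
        col = raw[t].str.strip()
        is_missing = col.isin(missing_tokens)
        parsed = pd.to_numeric(col.where(~is_missing), errors="coerce")
        bad = parsed.isna() & ~is_missing
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric score {raw[t].iloc[row]!r} in column {t!r}, "
                f"data row {row + 1}"
            )
        raw[t] = parsed
    age = pd.to_numeric(raw["age"].str.strip().replace(list(missing_tokens), np.nan),
                        errors="coerce")
    raw["age"] = age
    return CohortTable(raw, battery)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV readable by :func:`read_cohort` (missing -> empty cell)."""
    path = Path(path)
    cols = list(ID_COLUMNS) + cohort.battery.names
    # pandas writes the shortest round-trip repr of each float, so read/write
    # is the identity on values as well as on the missingness pattern
    cohort.data.loc[:, cols].to_csv(path, index=False, na_rep="", quoting=csv.QUOTE_MINIMAL)


def completeness_summary(cohort: CohortTable, battery: BatterySpec | None = None) -> CompletenessSummary:
    """Per-test missing fraction plus the complete-case count.

    The complete-case set (participants with no missing test anywhere in
    the battery) is the population used for composite scores and the
    multi-test count analyses.
    """
    battery = battery or cohort.battery
    if cohort.n == 0:
        raise ValidationError("completeness_summary requires a non-empty cohort")
    scores = cohort.data[battery.names]
    miss = scores.isna()
    frac = miss.mean(axis=0)
    frac.name = "missing_fraction"
    complete = int((~miss.any(axis=1)).sum())
    return CompletenessSummary(
        missing_fraction=frac,
        complete_cases=complete,
        n=cohort.n,
        missing_count=miss.sum(axis=0),
    )
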