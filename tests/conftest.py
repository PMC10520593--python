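import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cognorm import (
    BatterySpec,
    CohortTable,
    DeviationProfiles,
    TestSpec,
    fixture_pronia_like,
    generate_cohort,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def small_battery() -> BatterySpec:
    """Three tests: one reaction-time, one accuracy, one error count."""
    return BatterySpec.from_tests(
        [
            TestSpec("RT", "lower_better", 100.0),
            TestSpec("ACC", "higher_better"),
            TestSpec("ERR", "lower_better", 50.0),
        ]
    )


def make_cohort(battery: BatterySpec, rows: list[dict]) -> CohortTable:
    """Build a CohortTable from row dicts, filling id/demographic defaults."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "participant_id": row.get("participant_id", f"P{i + 1:03d}"),
            "group": row.get("group", "HC"),
            "site": row.get("site", "MAIN"),
            "age": row.get("age", 25.0),
            "sex": row.get("sex", "F"),
        }
        for t in battery.names:
            rec[t] = row.get(t, np.nan)
        records.append(rec)
    columns = ["participant_id", "group", "site", "age", "sex"] + battery.names
    return CohortTable(pd.DataFrame.from_records(records, columns=columns), battery)


def profiles_from_z(z: pd.DataFrame, group: pd.Series) -> DeviationProfiles:
    """Wrap a raw z matrix as DeviationProfiles (composite over complete rows)."""
    complete = ~z.isna().any(axis=1)
    return DeviationProfiles(
        z=z,
        composite=z.mean(axis=1).where(complete),
        complete_battery=complete,
        group=group,
    )


@pytest.fixture(scope="session")
def fixture_cohort() -> CohortTable:
    """One generated PRONIA-like cohort (1286 participants), shared per session."""
    return generate_cohort(fixture_pronia_like(), seed=123)
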