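"""Test-battery specification.

A battery is an ordered list of tests.  Each test has a scoring direction:
``higher_better`` scores (correct counts, d-prime, totals) are used as-is;
``lower_better`` scores (reaction times, error counts) are reversed against
a fixed per-test reference value before standardization, so that after
orientation a larger score always means better performance.

The reversal reference is a fixed instrument-level constant (e.g. the
discontinuation cap of a timed test), not the observed sample maximum:
a fixed reference keeps scoring deterministic and independent of cohort
composition, and any constant shift cancels in the z-score anyway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .errors import ConfigurationError

DIRECTIONS = ("higher_better", "lower_better")


@dataclass(frozen=True)
class TestSpec:
    """One test in the battery.

    Parameters
    ----------
    name
        Short unique identifier (column name in cohort files).
    direction
        ``higher_better`` or ``lower_better``.
    reversal_reference
        Raw-score value (test units) from which lower-is-better scores are
        subtracted.  Required iff ``direction == "lower_better"``.
    """

    name: str
    direction: str
    reversal_reference: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("test name must be non-empty")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(
                f"test {self.name!r}: direction must be one of {DIRECTIONS}, "
                f"got {self.direction!r}"
            )
        if self.direction == "lower_better" and self.reversal_reference is None:
            raise ConfigurationError(
                f"test {self.name!r}: lower_better tests require a reversal_reference"
            )
        if self.direction == "higher_better" and self.reversal_reference is not None:
            raise ConfigurationError(
                f"test {self.name!r}: higher_better tests must not set a reversal_reference"
            )


@dataclass(frozen=True)
class BatterySpec:
    """Ordered collection of :class:`TestSpec` with unique names."""

    tests: tuple[TestSpec, ...]

    def __post_init__(self) -> None:
        if len(self.tests) < 1:
            raise ConfigurationError("battery must contain at least one test")
        names = [t.name for t in self.tests]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate test names in battery: {dupes}")

    @classmethod
    def from_tests(cls, tests: Iterable[TestSpec]) -> "BatterySpec":
        return cls(tuple(tests))

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tests]

    def __iter__(self) -> Iterator[TestSpec]:
        return iter(self.tests)

    def __len__(self) -> int:
        return len(self.tests)

    def __getitem__(self, name: str) -> TestSpec:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(name)

    # ---- serialization -------------------------------------------------

    def to_records(self) -> list[dict]:
        recs = []
        for t in self.tests:
            rec: dict = {"name": t.name, "direction": t.direction}
            if t.reversal_reference is not None:
                rec["reversal_reference"] = t.reversal_reference
            recs.append(rec)
        return recs

    @classmethod
    def from_records(cls, records: list[dict]) -> "BatterySpec":
        tests = []
        for rec in records:
            try:
                tests.append(
                    TestSpec(
                        name=rec["name"],
                        direction=rec["direction"],
                        reversal_reference=rec.get("reversal_reference"),
                    )
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"battery record missing field {exc}: {rec!r}"
                ) from exc
        return cls.from_tests(tests)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_records(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_records(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "BatterySpec":
        path = Path(path)
        text = path.read_text()
        records = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(records, list):
            raise ConfigurationError(f"battery file {path} must contain a list of tests")
        return cls.from_records(records)


def default_battery() -> BatterySpec:
    """The packaged 12-test battery.

    Names follow the standard neuropsychological instruments (trail making,
    verbal fluency, continuous performance, list learning, figure recall,
    self-ordered pointing, digit spans, digit-symbol substitution, emotion
    recognition).  Reaction-time and error scores are lower-is-better; their
    reversal references are instrument caps (timed-test discontinuation at
    300 s, self-ordered-pointing error ceiling).
    """
    return BatterySpec.from_tests(
        [
            TestSpec("TMT_A", "lower_better", 300.0),
            TestSpec("TMT_B", "lower_better", 300.0),
            TestSpec("PVF", "higher_better"),
            TestSpec("SVF", "higher_better"),
            TestSpec("CPT", "higher_better"),
            TestSpec("RAVLT", "higher_better"),
            TestSpec("ROCF", "higher_better"),
            TestSpec("SOPT", "lower_better", 48.0),
            TestSpec("FDS", "higher_better"),
            TestSpec("BDS", "higher_better"),
            TestSpec("DSST", "higher_better"),
            TestSpec("DANVA", "higher_better"),
        ]
    )
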