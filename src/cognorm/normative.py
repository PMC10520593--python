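"""Orientation, normative model fitting, z-scores, and deviation profiles.

The normative model is the per-test mean and standard deviation of the
control group's oriented raw scores.  Every participant (controls
included) is standardized against it:

    z = (oriented raw − control mean) / control SD

so that z = −2 means two control standard deviations below the control
mean, regardless of the test's native units.  The composite score is the
arithmetic mean of all per-test z-scores and is defined only for
participants with a complete battery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .battery import BatterySpec
from .cohort import CohortTable
from .errors import ConfigurationError, DegenerateNormativeError, ValidationError


def orient_scores(cohort: CohortTable, battery: BatterySpec | None = None) -> CohortTable:
    """Reverse lower-is-better scores so larger always means better.

    For a lower_better test, oriented = reversal_reference − raw.  A raw
    score above the reversal reference violates the instrument cap and is
    an error naming the participant and test.  Missing values propagate.
    """
    battery = battery or cohort.battery
    df = cohort.data.copy()
    for t in battery:
        if t.direction != "lower_better":
            continue
        raw = df[t.name]
        over = raw > t.reversal_reference
        if over.any():
            pid = df.loc[over, "participant_id"].iloc[0]
            raise ValidationError(
                f"participant {pid!r}: raw score {raw[over].iloc[0]} on test "
                f"{t.name!r} exceeds its reversal reference {t.reversal_reference}"
            )
        df[t.name] = t.reversal_reference - raw
    return CohortTable(df, battery)


@dataclass(frozen=True)
class NormativeModel:
    """Per-test control mean/SD (oriented raw-score units) and control n.

    ``stats`` is indexed by test name with columns ``mu``, ``sigma``,
    ``n_control``.  ``sigma`` uses the sample (n−1) denominator.
    """

    stats: pd.DataFrame
    control_label: str = "HC"

    def __post_init__(self) -> None:
        for col in ("mu", "sigma", "n_control"):
            if col not in self.stats.columns:
                raise ConfigurationError(f"normative model missing column {col!r}")
        bad_sigma = self.stats.index[self.stats["sigma"] <= 0].tolist()
        if bad_sigma:
            raise DegenerateNormativeError(
                f"non-positive control SD for test(s): {bad_sigma}"
            )
        bad_n = self.stats.index[self.stats["n_control"] < 2].tolist()
        if bad_n:
            raise DegenerateNormativeError(
                f"fewer than 2 control observations for test(s): {bad_n}"
            )

    @property
    def tests(self) -> list[str]:
        return list(self.stats.index)

    def entry(self, test: str) -> tuple[float, float]:
        row = self.stats.loc[test]
        return float(row["mu"]), float(row["sigma"])

    # ---- persistence: {test: {mu, sigma, n_control}} -------------------

    def to_mapping(self) -> dict:
        return {
            t: {
                "mu": float(r["mu"]),
                "sigma": float(r["sigma"]),
                "n_control": int(r["n_control"]),
            }
            for t, r in self.stats.iterrows()
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {"control_label": self.control_label, "tests": self.to_mapping()}
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "NormativeModel":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        stats = pd.DataFrame.from_dict(payload["tests"], orient="index")
        stats.index.name = "test"
        return cls(stats=stats, control_label=payload.get("control_label", "HC"))


def fit_normative(oriented: CohortTable, control_label: str = "HC") -> NormativeModel:
    """Fit per-test control mean/SD on all non-missing control observations.

    Uses pairwise-complete control data per test (not complete cases only),
    which maximizes normative precision.  A test with fewer than two
    control observations or zero control variance cannot anchor a z-scale
    and raises :class:`DegenerateNormativeError`.
    """
    oriented.require_group(control_label)
    ctrl = oriented.data.loc[oriented.data["group"] == control_label, oriented.battery.names]
    rows = {}
    for t in oriented.battery.names:
        vals = ctrl[t].dropna().to_numpy()
        if len(vals) < 2:
            raise DegenerateNormativeError(
                f"test {t!r}: only {len(vals)} non-missing control observation(s)"
            )
        sigma = float(np.std(vals, ddof=1))
        if sigma == 0.0:
            raise DegenerateNormativeError(f"test {t!r}: zero control variance")
        rows[t] = {"mu": float(np.mean(vals)), "sigma": sigma, "n_control": len(vals)}
    stats = pd.DataFrame.from_dict(rows, orient="index").loc[oriented.battery.names]
    stats.index.name = "test"
    return NormativeModel(stats=stats, control_label=control_label)


def zscore(oriented_raw, mu: float, sigma: float):
    """(oriented raw − control mean) / control SD; NaN propagates."""
    if sigma <= 0:
        raise DegenerateNormativeError("sigma must be positive")
    return (oriented_raw - mu) / sigma


@dataclass
class DeviationProfiles:
    """Per-participant z-scores, composite, and completeness flags.

    ``z`` is indexed by participant_id (battery order columns, NaN =
    missing); ``composite`` is the mean of all per-test z-scores, defined
    only where ``complete_battery`` is True; ``group`` carries the group
    label for downstream aggregation.
    """

    z: pd.DataFrame
    composite: pd.Series
    complete_battery: pd.Series
    group: pd.Series

    @property
    def n(self) -> int:
        return len(self.z)

    def for_groups(self, labels) -> "DeviationProfiles":
        mask = self.group.isin(list(labels))
        return replace(
            self,
            z=self.z.loc[mask],
            composite=self.composite.loc[mask],
            complete_battery=self.complete_battery.loc[mask],
            group=self.group.loc[mask],
        )


def profile(
    cohort: CohortTable,
    battery: BatterySpec | None = None,
    model: NormativeModel | None = None,
) -> DeviationProfiles:
    """Standardize an *oriented* cohort against a normative model.

    ``model`` must cover every battery test.  The composite is the mean of
    the full z vector and is missing for any participant with at least one
    missing test.
    """
    battery = battery or cohort.battery
    if model is None:
        raise ConfigurationError("profile requires a fitted NormativeModel")
    not_covered = [t for t in battery.names if t not in model.tests]
    if not_covered:
        raise ConfigurationError(f"normative model does not cover test(s): {not_covered}")

    scores = cohort.scores
    mu = model.stats.loc[battery.names, "mu"]
    sigma = model.stats.loc[battery.names, "sigma"]
    z = (scores - mu) / sigma
    complete = ~z.isna().any(axis=1)
    composite = z.mean(axis=1).where(complete)
    group = cohort.data.set_index("participant_id")["group"]
    return DeviationProfiles(
        z=z, composite=composite, complete_battery=complete, group=group
    )
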