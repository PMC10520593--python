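"""Five-band severity classification and prevalence summaries.

z-scores are classified into five bands relative to the control
distribution:

====================  =====================
band                  z range
====================  =====================
severely impaired     z < −2
moderately impaired   −2 ≤ z < −1
average               −1 ≤ z ≤ 1
above average         1 < z ≤ 2
extremely high        z > 2
====================  =====================

The bands partition the real line; ties at ±1 fall in the average band and
ties at ±2 in the moderate bands (the strict ">2 SD" reading of the outer
bands).  Multi-test criteria ("impaired on at least k tests at level L")
default to *cumulative* counting — a severe deviation also counts as
moderate-or-worse — which makes prevalence nested across levels; an
exclusive per-band mode is available for sensitivity analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .normative import DeviationProfiles

COMPOSITE = "composite"


class Band(enum.Enum):
    SEVERE_IMPAIR = "severely impaired"
    MODERATE_IMPAIR = "moderately impaired"
    AVERAGE = "average"
    ABOVE_AVERAGE = "above average"
    EXTREMELY_HIGH = "extremely high"


#: Bands from worst to best, the presentation order of all reports.
BAND_ORDER = [
    Band.SEVERE_IMPAIR,
    Band.MODERATE_IMPAIR,
    Band.AVERAGE,
    Band.ABOVE_AVERAGE,
    Band.EXTREMELY_HIGH,
]


def band_of(z: float) -> Band | None:
    """Band of a single z-score; NaN (missing) maps to None."""
    if z is None or (isinstance(z, float) and np.isnan(z)):
        return None
    if not np.isfinite(z):
        raise ValidationError(f"z must be finite, got {z}")
    if z < -2:
        return Band.SEVERE_IMPAIR
    if z < -1:
        return Band.MODERATE_IMPAIR
    if z <= 1:
        return Band.AVERAGE
    if z <= 2:
        return Band.ABOVE_AVERAGE
    return Band.EXTREMELY_HIGH


def assign_bands(z: pd.DataFrame | pd.Series):
    """Vectorized :func:`band_of`; missing z stays missing."""
    arr = np.asarray(z, dtype=float)
    out = np.select(
        [arr < -2, arr < -1, arr <= 1, arr <= 2, arr > 2],
        [
            Band.SEVERE_IMPAIR,
            Band.MODERATE_IMPAIR,
            Band.AVERAGE,
            Band.ABOVE_AVERAGE,
            Band.EXTREMELY_HIGH,
        ],
        default=None,
    )
    out = np.where(np.isnan(arr), None, out)
    if isinstance(z, pd.DataFrame):
        return pd.DataFrame(out, index=z.index, columns=z.columns)
    if isinstance(z, pd.Series):
        return pd.Series(out, index=z.index)
    return out


def _group_order(group: pd.Series) -> list[str]:
    return list(dict.fromkeys(group))


def band_prevalence(profiles: DeviationProfiles) -> pd.DataFrame:
    """Per-group, per-measure band counts and percentages.

    Measures are every battery test plus the composite.  Denominators are
    the per-test non-missing counts (composite: complete cases); an empty
    group/measure cell yields an undefined (NaN) percentage, never 0.

    Returns a tidy frame: group, measure, band, count, n, percent.
    """
    measures = {t: profiles.z[t] for t in profiles.z.columns}
    measures[COMPOSITE] = profiles.composite
    rows = []
    for g in _group_order(profiles.group):
        in_g = profiles.group == g
        for name, values in measures.items():
            vals = values.loc[in_g].dropna()
            bands = assign_bands(vals)
            n = len(vals)
            for band in BAND_ORDER:
                count = int((bands == band).sum())
                pct = 100.0 * count / n if n > 0 else np.nan
                rows.append(
                    {
                        "group": g,
                        "measure": name,
                        "band": band.value,
                        "count": count,
                        "n": n,
                        "percent": pct,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CriterionSpec:
    """A multi-test qualification rule.

    side
        ``impairment`` (z at or below −level) or ``strength`` (at or above
        +level).
    level
        Threshold L in control-SD units (1 or 2 in the standard reports).
    min_tests
        Minimum number of qualifying tests k (default 2).
    mode
        ``cumulative`` counts any deviation at least as extreme as the
        level; ``band_exclusive`` counts only the level's own band
        (moderate band for L=1, the open tail for L=2).
    population
        ``complete_cases`` (default; participants with a full battery) or
        ``per_test_available`` (everyone, counting over non-missing tests).
    """

    side: str = "impairment"
    level: float = 1.0
    min_tests: int = 2
    mode: str = "cumulative"
    population: str = "complete_cases"

    def __post_init__(self) -> None:
        if self.side not in ("impairment", "strength"):
            raise ConfigurationError(f"side must be impairment|strength, got {self.side!r}")
        if self.level <= 0:
            raise ConfigurationError("level must be positive")
        if self.min_tests < 1:
            raise ConfigurationError("min_tests must be >= 1")
        if self.mode not in ("cumulative", "band_exclusive"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "band_exclusive" and self.level not in (1.0, 2.0):
            raise ConfigurationError("band_exclusive mode is defined for levels 1 and 2 only")
        if self.population not in ("complete_cases", "per_test_available"):
            raise ConfigurationError(f"unknown population {self.population!r}")


def _qualifies(z: np.ndarray, spec: CriterionSpec) -> np.ndarray:
    """Boolean array: does each z qualify at the spec's side/level/mode?

    NaN never qualifies.
    """
    with np.errstate(invalid="ignore"):
        if spec.mode == "cumulative":
            return (z <= -spec.level) if spec.side == "impairment" else (z >= spec.level)
        if spec.level == 1.0:
            if spec.side == "impairment":
                return (z >= -2) & (z < -1)
            return (z > 1) & (z <= 2)
        return (z < -2) if spec.side == "impairment" else (z > 2)


def meets_criterion(z_values, spec: CriterionSpec) -> bool:
    """Does one participant's z vector qualify on at least ``min_tests`` tests?

    ``z_values`` is the participant's per-test z vector (NaN = missing).
    Under the ``complete_cases`` population a profile with any missing test
    does not satisfy the population rule and returns False.
    """
    z = np.asarray(z_values, dtype=float)
    if spec.population == "complete_cases" and np.isnan(z).any():
        return False
    return int(_qualifies(z, spec).sum()) >= spec.min_tests


@dataclass
class CriterionPrevalence:
    """Prevalence of a multi-test criterion, per group."""

    spec: CriterionSpec
    summary: pd.DataFrame      # group, n, count, percent
    distribution: pd.DataFrame  # group x number-of-qualifying-tests (0..m)


def qualifying_counts(profiles: DeviationProfiles, spec: CriterionSpec) -> pd.Series:
    """Per-participant count of qualifying tests, over the spec's population."""
    if spec.population == "complete_cases":
        z = profiles.z.loc[profiles.complete_battery]
    else:
        z = profiles.z
    q = _qualifies(z.to_numpy(dtype=float), spec)
    return pd.Series(q.sum(axis=1), index=z.index, name="n_qualifying")


def criterion_prevalence(profiles: DeviationProfiles, spec: CriterionSpec) -> CriterionPrevalence:
    """Per-group percentage meeting the criterion, plus the full count distribution."""
    counts = qualifying_counts(profiles, spec)
    group = profiles.group.loc[counts.index]
    m = profiles.z.shape[1]
    order = _group_order(profiles.group)
    rows, dist_rows = [], []
    for g in order:
        gc = counts.loc[group == g]
        n = len(gc)
        k_met = int((gc >= spec.min_tests).sum())
        rows.append(
            {
                "group": g,
                "n": n,
                "count": k_met,
                "percent": 100.0 * k_met / n if n else np.nan,
            }
        )
        dist = gc.value_counts().reindex(range(m + 1), fill_value=0)
        dist_rows.append(dist.rename(g))
    summary = pd.DataFrame(rows)
    distribution = pd.DataFrame(dist_rows)
    distribution.index.name = "group"
    distribution.columns.name = "n_qualifying"
    return CriterionPrevalence(spec=spec, summary=summary, distribution=distribution)


def mean_tests_at_level(
    profiles: DeviationProfiles,
    side: str = "impairment",
    level: float = 1.0,
    mode: str = "cumulative",
    population: str = "complete_cases",
) -> pd.DataFrame:
    """Per-group mean and SD of the number of qualifying tests.

    Defaults to complete cases so every group mean is computed over the
    same per-participant battery length.
    """
    spec = CriterionSpec(side=side, level=level, min_tests=1, mode=mode, population=population)
    counts = qualifying_counts(profiles, spec)
    group = profiles.group.loc[counts.index]
    rows = []
    for g in _group_order(profiles.group):
        gc = counts.loc[group == g].to_numpy(dtype=float)
        rows.append(
            {
                "group": g,
                "n": len(gc),
                "mean": float(np.mean(gc)) if len(gc) else np.nan,
                "sd": float(np.std(gc, ddof=1)) if len(gc) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
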