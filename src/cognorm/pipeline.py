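"""End-to-end analysis: orient, fit norms, profile, summarize, test.

:func:`run_analysis` is the single entry point used by the CLI, the
analysis scripts, and the acceptance checks.  It produces the standard
report tables:

* ``bands`` — per group and measure (each test + composite), the count and
  percentage in each of the five severity bands;
* ``criteria`` — per group, side (impairment/strength) and level (1, 2 SD),
  the percentage qualifying on >= k tests;
* ``distribution`` — the full per-group distribution of the number of
  qualifying tests;
* ``mean_counts`` — per group mean/SD of the number of qualifying tests;
* ``any_level`` — per group and test, the share with any deviation beyond
  1 SD (the "any impairment / any strength" aggregation);
* ``inference`` — tidy hypothesis-test table: omnibus chi-square per
  measure and level, Bonferroni pairwise post-hocs, odds ratios of any
  impairment (clinical vs control), and the ANOVA + Tamhane T2 post-hocs
  on the qualifying-test counts.

Every table carries the denominator (n) each cell was computed on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import (
    COMPOSITE,
    CriterionSpec,
    band_prevalence,
    criterion_prevalence,
    mean_tests_at_level,
    qualifying_counts,
)
from .battery import BatterySpec
from .cohort import CohortTable, completeness_summary
from .errors import ValidationError
from .inference import (
    chi_square,
    odds_ratio,
    one_way_anova,
    posthoc_means,
    posthoc_proportions,
)
from .normative import DeviationProfiles, fit_normative, orient_scores, profile

log = logging.getLogger("cognorm")

_INFER_COLS = [
    "measure", "side", "level", "comparison", "method", "statistic", "df",
    "p_value", "adjusted_p", "or_point", "ci_low", "ci_high", "n",
]


@dataclass
class AnalysisResult:
    bands: pd.DataFrame
    criteria: pd.DataFrame
    distribution: pd.DataFrame
    mean_counts: pd.DataFrame
    any_level: pd.DataFrame
    inference: pd.DataFrame
    denominators: dict = field(default_factory=dict)

    TABLES = ("bands", "criteria", "distribution", "mean_counts", "any_level", "inference")


def _measure_flags(profiles: DeviationProfiles, measure: str, side: str, level: float):
    """Per-group boolean qualification arrays for one measure (cumulative)."""
    values = profiles.composite if measure == COMPOSITE else profiles.z[measure]
    flags = {}
    for g in dict.fromkeys(profiles.group):
        vals = values.loc[profiles.group == g].dropna().to_numpy()
        flags[g] = vals <= -level if side == "impairment" else vals >= level
    return flags


def _flag_table(flags: dict[str, np.ndarray]) -> np.ndarray:
    return np.array(
        [[f.sum(), (~f).sum()] for f in flags.values()], dtype=float
    )


def run_analysis(
    cohort: CohortTable,
    battery: BatterySpec | None = None,
    control_label: str = "HC",
    levels: tuple[float, ...] = (1.0, 2.0),
    min_tests: int = 2,
    mode: str = "cumulative",
    population: str = "complete_cases",
) -> AnalysisResult:
    """Run the full profiling analysis on a raw cohort."""
    battery = battery or cohort.battery
    cohort.require_group(control_label)
    oriented = orient_scores(cohort, battery)
    model = fit_normative(oriented, control_label)
    profiles = profile(oriented, battery, model)
    comp = completeness_summary(cohort, battery)
    groups = list(dict.fromkeys(profiles.group))
    clinical = [g for g in groups if g != control_label]
    if not clinical:
        log.warning("cohort contains only the control group %r; "
                    "clinical comparisons will be empty", control_label)

    bands = band_prevalence(profiles)

    crit_rows, dist_rows, mean_rows = [], [], []
    counts_by = {}
    for side in ("impairment", "strength"):
        for level in levels:
            spec = CriterionSpec(side=side, level=level, min_tests=min_tests,
                                 mode=mode, population=population)
            prev = criterion_prevalence(profiles, spec)
            s = prev.summary.copy()
            s.insert(0, "side", side)
            s.insert(1, "level", level)
            crit_rows.append(s)
            d = prev.distribution.reset_index().melt(
                id_vars="group", var_name="n_qualifying", value_name="count"
            )
            d.insert(0, "side", side)
            d.insert(1, "level", level)
            dist_rows.append(d)
            mc = mean_tests_at_level(profiles, side=side, level=level,
                                     mode=mode, population=population)
            mc.insert(0, "side", side)
            mc.insert(1, "level", level)
            mean_rows.append(mc)
            counts_spec = CriterionSpec(side=side, level=level, min_tests=1,
                                        mode=mode, population=population)
            counts_by[(side, level)] = qualifying_counts(profiles, counts_spec)
    criteria = pd.concat(crit_rows, ignore_index=True)
    distribution = pd.concat(dist_rows, ignore_index=True)
    mean_counts = pd.concat(mean_rows, ignore_index=True)

    # Figure-1-style any-deviation view (per-test available denominators)
    any_rows = []
    for side in ("impairment", "strength"):
        for t in battery.names:
            flags = _measure_flags(profiles, t, side, 1.0)
            for g in groups:
                f = flags[g]
                n = len(f)
                any_rows.append({
                    "group": g, "measure": t, "side": side,
                    "count": int(f.sum()), "n": n,
                    "percent": 100.0 * f.sum() / n if n else np.nan,
                })
    any_level = pd.DataFrame(any_rows)

    inference = _inference_table(profiles, battery, control_label, clinical,
                                 levels, counts_by)

    denominators = {
        "n_total": cohort.n,
        "complete_cases": comp.complete_cases,
        "per_test_n": {t: int(cohort.n - comp.missing_count[t]) for t in battery.names},
        "groups": {g: int((profiles.group == g).sum()) for g in groups},
    }
    log.info("analysis denominators: total n=%d, complete cases=%d",
             cohort.n, comp.complete_cases)
    return AnalysisResult(
        bands=bands, criteria=criteria, distribution=distribution,
        mean_counts=mean_counts, any_level=any_level, inference=inference,
        denominators=denominators,
    )


def _inference_table(profiles, battery, control_label, clinical, levels, counts_by):
    rows: list[dict] = []

    def add(measure, side, level, comparison, method, *, statistic=np.nan,
            df=np.nan, p=np.nan, adj=np.nan, orp=np.nan, lo=np.nan, hi=np.nan, n=np.nan):
        rows.append({
            "measure": measure, "side": side, "level": level,
            "comparison": comparison, "method": method, "statistic": statistic,
            "df": df, "p_value": p, "adjusted_p": adj, "or_point": orp,
            "ci_low": lo, "ci_high": hi, "n": n,
        })

    measures = battery.names + [COMPOSITE]
    n_groups = len(clinical) + 1
    m_pairs = n_groups * (n_groups - 1) // 2

    for measure in measures:
        for side in ("impairment", "strength"):
            for level in levels:
                flags = _measure_flags(profiles, measure, side, level)
                flags = {g: f for g, f in flags.items() if len(f) > 0}
                n_used = int(sum(len(f) for f in flags.values()))
                if len(flags) >= 2:
                    table = _flag_table(flags)
                    try:
                        res = chi_square(table)
                        add(measure, side, level, "omnibus", res.method,
                            statistic=res.statistic, df=res.df, p=res.p_value,
                            n=n_used)
                    except ValidationError:
                        # no variation in qualification anywhere: test undefined
                        add(measure, side, level, "omnibus",
                            "pearson_chi_square(undefined)", n=n_used)
                    pair_tables = {}
                    names = list(flags)
                    for i, g1 in enumerate(names):
                        for g2 in names[i + 1:]:
                            pair_tables[f"{g1}_vs_{g2}"] = np.array(
                                [[flags[g1].sum(), (~flags[g1]).sum()],
                                 [flags[g2].sum(), (~flags[g2]).sum()]], dtype=float)
                    for label, tab in pair_tables.items():
                        try:
                            (res,) = posthoc_proportions({label: tab}, m=m_pairs)
                            add(measure, side, level, label, res.method,
                                statistic=res.statistic, df=res.df,
                                p=res.p_value, adj=res.adjusted_p,
                                n=int(tab.sum()))
                        except ValidationError:
                            add(measure, side, level, label,
                                "pearson_chi_square(undefined)", n=int(tab.sum()))
        # odds of any impairment (beyond 1 SD), clinical vs control
        flags = _measure_flags(profiles, measure, "impairment", 1.0)
        if control_label in flags and len(flags[control_label]) > 0:
            c = flags[control_label]
            for g in clinical:
                f = flags.get(g)
                if f is None or len(f) == 0:
                    continue
                try:
                    res = odds_ratio(f.sum(), (~f).sum(), c.sum(), (~c).sum())
                    add(measure, "impairment", 1.0, f"{g}_vs_{control_label}",
                        "odds_ratio_altman"
                        + ("+haldane" if res.continuity_corrected else ""),
                        orp=res.or_point, lo=res.ci_low, hi=res.ci_high,
                        n=int(len(f) + len(c)))
                except ValidationError:
                    add(measure, "impairment", 1.0, f"{g}_vs_{control_label}",
                        "odds_ratio(undefined)", n=int(len(f) + len(c)))

    # ANOVA + Tamhane T2 on the qualifying-test counts
    for (side, level), counts in counts_by.items():
        group = profiles.group.loc[counts.index]
        by_group = {g: counts.loc[group == g].to_numpy(dtype=float)
                    for g in dict.fromkeys(profiles.group)}
        by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
        if len(by_group) < 2:
            continue
        try:
            res = one_way_anova(list(by_group.values()))
            add("n_qualifying", side, level, "omnibus", res.method,
                statistic=res.statistic, df=f"{int(res.df[0])},{int(res.df[1])}",
                p=res.p_value, n=int(sum(len(v) for v in by_group.values())))
            for pr in posthoc_means(by_group, method="tamhane"):
                add("n_qualifying", side, level, pr.comparison, pr.method,
                    statistic=pr.statistic, df=pr.df, p=pr.p_value,
                    adj=pr.adjusted_p, lo=pr.ci_low, hi=pr.ci_high,
                    n=int(sum(len(by_group[g]) for g in pr.comparison.split("_vs_"))))
                rows[-1]["or_point"] = np.nan
                rows[-1]["estimate"] = pr.estimate
        except ValidationError as exc:
            log.warning("count ANOVA skipped for %s level %s: %s", side, level, exc)

    df = pd.DataFrame(rows)
    for c in _INFER_COLS:
        if c not in df.columns:
            df[c] = np.nan
    cols = _INFER_COLS + [c for c in df.columns if c not in _INFER_COLS]
    return df[cols] if len(df) else pd.DataFrame(columns=_INFER_COLS)


def write_analysis(result: AnalysisResult, outdir: str | Path,
                   provenance: dict | None = None) -> list[Path]:
    """Write each table as CSV with provenance comment headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header_lines = [f"# {k}: {v}" for k, v in (provenance or {}).items()]
    header_lines.append(f"# denominators: {result.denominators}")
    written = []
    for name in AnalysisResult.TABLES:
        table: pd.DataFrame = getattr(result, name)
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(line + "\n")
            table.to_csv(fh, index=False)
        written.append(path)
    return written


def read_analysis_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
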