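"""Between-group statistics: odds ratios, chi-square, ANOVA, post-hocs.

The odds ratio follows Altman's log-scale construction: for a 2x2 table
(a = clinical impaired, b = clinical not, c = control impaired,
d = control not),

    OR = (a d)/(b c),   SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d),
    95% CI = exp(ln OR +/- 1.96 SE).

A table containing a zero cell gets the Haldane–Anscombe correction
(0.5 added to every cell) and is flagged.  Omnibus group differences in
proportions use the Pearson chi-square without continuity correction;
pairwise post-hocs apply a Bonferroni multiplier.  Continuous outcomes use
one-way ANOVA with either Bonferroni (pooled-variance t) or Tamhane T2
(Welch t with Sidak-type adjustment) pairwise follow-ups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

Z_95 = 1.96  # normal quantile used in the Altman CI


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValidationError("odds-ratio CI must bracket the point estimate")


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis test: statistic, degrees of freedom, p-values."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str
    adjusted_p: float | None = None
    comparison: str | None = None
    estimate: float | None = None   # e.g. mean difference for pairwise tests
    ci_low: float | None = None
    ci_high: float | None = None


def odds_ratio(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Altman odds ratio with 95% CI for a 2x2 table (a,b clinical; c,d control)."""
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or not np.all(np.isfinite(cells)):
        raise ValidationError("odds_ratio requires four finite non-negative cells")
    if cells.sum() == 0:
        raise ValidationError("odds_ratio is undefined on an all-zero table")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_point = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    log_or = math.log(or_point)
    return OddsRatioResult(
        or_point=or_point,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        continuity_corrected=corrected,
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c count table (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.size == 0:
        raise ValidationError("chi_square requires a 2-D count table")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValidationError("chi_square requires a positive grand total")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError("chi_square table has an all-zero row or column")
    res = stats.chi2_contingency(obs, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(res.pvalue),
        method="pearson_chi_square",
    )


def posthoc_proportions(tables: dict[str, "np.ndarray"], m: int | None = None) -> list[TestResult]:
    """Pairwise 2x2 chi-squares with Bonferroni-adjusted p (capped at 1).

    ``tables`` maps a comparison label (e.g. ``"ROP_vs_HC"``) to its 2x2
    table; ``m`` defaults to the number of comparisons supplied.
    """
    if not tables:
        raise ValidationError("posthoc_proportions requires at least one table")
    m = m if m is not None else len(tables)
    if m < 1:
        raise ValidationError("multiplicity m must be >= 1")
    out = []
    for label, table in tables.items():
        res = chi_square(table)
        out.append(
            TestResult(
                statistic=res.statistic,
                df=res.df,
                p_value=res.p_value,
                adjusted_p=min(1.0, m * res.p_value),
                method="pearson_chi_square+bonferroni",
                comparison=label,
            )
        )
    return out


def pairwise_impairment_tables(flags: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """All pairwise 2x2 (group x qualifies) tables from per-group boolean arrays."""
    out = {}
    for g1, g2 in itertools.combinations(flags, 2):
        f1 = np.asarray(flags[g1], dtype=bool)
        f2 = np.asarray(flags[g2], dtype=bool)
        out[f"{g1}_vs_{g2}"] = np.array(
            [[f1.sum(), (~f1).sum()], [f2.sum(), (~f2).sum()]], dtype=float
        )
    return out


def one_way_anova(groups) -> TestResult:
    """Classical one-way ANOVA over >=2 groups of >=2 values each."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("one_way_anova requires >=2 groups with >=2 values each")
    if all(np.var(a) == 0 for a in arrays):
        raise ValidationError("one_way_anova is degenerate: zero within-group variance everywhere")
    f, p = stats.f_oneway(*arrays)
    g = len(arrays)
    n = sum(len(a) for a in arrays)
    return TestResult(
        statistic=float(f), df=(float(g - 1), float(n - g)), p_value=float(p),
        method="one_way_anova",
    )


def _pairwise_pooled_t(x: np.ndarray, y: np.ndarray):
    """Pooled-variance two-sample t: statistic, df, p, mean diff, SE."""
    nx, ny = len(x), len(y)
    diff = float(np.mean(x) - np.mean(y))
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    t = diff / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p, diff, se


def _pairwise_welch_t(x: np.ndarray, y: np.ndarray):
    """Welch two-sample t with Welch–Satterthwaite df."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1) / nx, np.var(y, ddof=1) / ny
    diff = float(np.mean(x) - np.mean(y))
    se = math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    t = diff / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p, diff, se


def posthoc_means(groups: dict[str, "np.ndarray"], method: str = "tamhane") -> list[TestResult]:
    """Pairwise mean comparisons after ANOVA.

    ``bonferroni``: pooled-variance t per pair, adjusted_p = min(1, m p),
    CI at the Bonferroni-adjusted level (alpha/m).
    ``tamhane`` (T2): Welch t per pair with Welch–Satterthwaite df and a
    Sidak-type adjustment, adjusted_p = 1 − (1 − p)^m, CI at the
    Sidak-adjusted level.  Both return the mean difference and its CI.
    """
    if method not in ("bonferroni", "tamhane"):
        raise ValidationError(f"unknown post-hoc method {method!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("posthoc_means requires >=2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise ValidationError("each group needs >=2 values")
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    alpha = 0.05
    out = []
    for g1, g2 in pairs:
        x, y = arrays[g1], arrays[g2]
        if method == "bonferroni":
            t, df, p, diff, se = _pairwise_pooled_t(x, y)
            adj_p = min(1.0, m * p)
            crit = stats.t.ppf(1 - (alpha / m) / 2, df)
        else:
            t, df, p, diff, se = _pairwise_welch_t(x, y)
            adj_p = min(1.0, 1.0 - (1.0 - p) ** m)
            adj_p = max(adj_p, p)  # guard against fp rounding for tiny p
            alpha_sidak = 1.0 - (1.0 - alpha) ** (1.0 / m)
            crit = stats.t.ppf(1 - alpha_sidak / 2, df)
        out.append(
            TestResult(
                statistic=float(t),
                df=float(df),
                p_value=float(p),
                adjusted_p=float(adj_p),
                method=method,
                comparison=f"{g1}_vs_{g2}",
                estimate=diff,
                ci_low=diff - crit * se,
                ci_high=diff + crit * se,
            )
        )
    return out
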