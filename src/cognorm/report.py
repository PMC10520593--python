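"""Markdown rendering of the analysis tables.

Percentages are shown to one decimal, statistics to three, p-values to
three with a ``<0.001`` floor — the conventional presentation for this
kind of normative-prevalence report.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pipeline import AnalysisResult, read_analysis_table

_SECTIONS = [
    ("bands", "Severity-band prevalence per test"),
    ("criteria", "Multi-test criterion prevalence"),
    ("distribution", "Distribution of the number of qualifying tests"),
    ("mean_counts", "Mean number of qualifying tests"),
    ("any_level", "Any impairment / any strength (beyond 1 SD) per test"),
    ("inference", "Group-comparison statistics"),
]


def _fmt(value, col: str) -> str:
    if isinstance(value, float) and np.isnan(value):
        return ""
    if col == "percent":
        return f"{value:.1f}"
    if col in ("p_value", "adjusted_p"):
        return "<0.001" if value < 0.001 else f"{value:.3f}"
    if col in ("statistic", "or_point", "ci_low", "ci_high", "mean", "sd", "estimate"):
        return f"{value:.3f}"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def _table_md(df: pd.DataFrame) -> str:
    if len(df) == 0:
        return "_no data_\n"
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(_fmt(row[c], c) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render_report(analysis_dir: str | Path) -> str:
    """Render one markdown document from a directory of analysis CSVs."""
    analysis_dir = Path(analysis_dir)
    missing = [n for n, _ in _SECTIONS
               if not (analysis_dir / f"{n}.csv").exists()]
    if missing:
        raise ConfigurationError(
            f"analysis directory {analysis_dir} is missing table(s): {missing}"
        )
    parts = ["# Cognitive deviation profile report\n"]
    for name, title in _SECTIONS:
        df = read_analysis_table(analysis_dir / f"{name}.csv")
        parts.append(f"## {title}\n")
        parts.append(_table_md(df))
    return "\n".join(parts)


def render_result(result: AnalysisResult) -> str:
    """Render directly from an in-memory :class:`AnalysisResult`."""
    parts = ["# Cognitive deviation profile report\n"]
    for name, title in _SECTIONS:
        parts.append(f"## {title}\n")
        parts.append(_table_md(getattr(result, name)))
    return "\n".join(parts)
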