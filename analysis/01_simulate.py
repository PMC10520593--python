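"""Generate the default synthetic cohort and document its missingness.

Writes results/cohort.csv (1286 participants: HC 454, CHR 270, ROD 267,
ROP 295) plus the generating config, and prints the per-test missing
fractions so the site-block gap on the list-learning test is visible.
"""

from pathlib import Path

from cognorm import completeness_summary, fixture_pronia_like, generate_cohort, write_cohort

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = fixture_pronia_like(seed=SEED)
    cfg.save(RESULTS / "sim_config.yaml")
    cohort = generate_cohort(cfg)
    write_cohort(cohort, RESULTS / "cohort.csv")

    comp = completeness_summary(cohort)
    print(f"cohort: n={cohort.n}, groups={ {g: int((cohort.data.group == g).sum()) for g in cohort.groups} }")
    print("\nper-test missing fraction:")
    print(comp.missing_fraction.round(3).to_string())
    blocked = cfg.site_block.test
    print(f"\n{blocked} missingness {comp.missing_fraction[blocked]:.3f} "
          f"comes from the {cfg.site_block.site} site block (configured share "
          f"{cfg.site_block.share}); all other tests lose 0.7-5.4% at random.")
    print(f"complete cases (no missing test): {comp.complete_cases} of {cohort.n}")


if __name__ == "__main__":
    main()
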