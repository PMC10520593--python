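"""Render the markdown report from the analysis tables.

Writes results/report.md — one document with the band-prevalence,
criterion, mean-count, any-deviation, and inference tables.
"""

from pathlib import Path

from cognorm import render_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    md = render_report(RESULTS / "analysis")
    out = RESULTS / "report.md"
    out.write_text(md)
    n_sections = md.count("\n## ")
    print(f"wrote {out} ({n_sections} sections, {len(md.splitlines())} lines)")


if __name__ == "__main__":
    main()
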