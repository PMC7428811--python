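"""Reproduce the full scaling-results table.

Carries each mouse baseline to human and blue-whale size/longevity,
evaluates the unmitigated lifetime risk (it saturates at ~100%
everywhere), and solves the four evolutionary hypotheses — mutation-rate
fold-reduction, immune policing of cancer cells, immune policing of
driver-bearing cells, and added driver mutations — for the change that
restores the 1% risk.  Writes results/table2.csv and results/table2.md.
"""

from pathlib import Path

import petostage as ps
from petostage.report import table_to_frame, write_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = ps.build_table2()
    df = table_to_frame(rows)
    OUT.mkdir(exist_ok=True)
    write_table(df, OUT / "table2.csv", "csv")
    display = df[[c for c in df.columns if not c.endswith("_full")]]
    write_table(display, OUT / "table2.md", "md")

    print(write_table(display, None, "md"))
    worst = max(abs(a - 0.01) for r in rows for a in r.achieved_risks)
    print(f"{len(rows)} scenarios; every unmitigated risk >= "
          f"{min(r.unmitigated_risk for r in rows):.4f} ('100%'); all four "
          f"solutions per row re-evaluate to 1% (worst deviation "
          f"{worst:.1e}).")
    print("Wrote", OUT / "table2.csv", "and", OUT / "table2.md")


if __name__ == "__main__":
    main()
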