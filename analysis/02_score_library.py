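"""Score the synthetic screening library and report its grade distribution.

Runs the dedup filter and the seven-criterion weighted scorer over
results/synthetic/library.csv, then prints the grade distribution the way a
screening campaign reports it (counts, percentages, mean/median total).
A-grade compounds (S_total ≥ 0.85) are the docking candidates.
"""

import json
from pathlib import Path

from gradescreen.compound_io import filter_valid_unique, parse_compound_table
from gradescreen.druglikeness import (
    scorecards_to_frame,
    score_compound,
    summarize_library,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = parse_compound_table(ROOT / "synthetic" / "library.csv", "csv")
    kept, log = filter_valid_unique(records)
    print(f"{len(records)} records; {len(kept)} unique valid structures "
          f"({len(log)} removed: {log.counts()})")

    cards = [score_compound(rec) for rec in kept]
    frame = scorecards_to_frame(cards)
    frame.to_csv(ROOT / "scorecards.csv", index=False)

    s = summarize_library(cards)
    (ROOT / "grade_summary.json").write_text(json.dumps({
        "n": s.n, "counts": s.counts, "percentages": s.percentages,
        "mean_total": s.mean_total, "median_total": s.median_total,
    }, indent=2))
    print(f"grade distribution over {s.n} unique compounds:")
    for g in "ABCDF":
        print(f"  {g}: n={s.counts[g]:3d}  {s.percentages[g]:5.1f}%")
    print(f"mean S_total {s.mean_total:.3f}, median {s.median_total:.3f}")
    n_a = s.counts["A"]
    print(f"-> {n_a} A-grade compounds advance to docking")


if __name__ == "__main__":
    main()
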