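#!/usr/bin/env python
"""Apply the exclusion rules and summarize the analysis cohort.

Reads results/colony/colony.csv, drops breeders, date errors, under-age
records, rapid-loss mice (>20% monthly loss) and short series (<3 points),
and writes the exclusion report plus cohort composition tables under
results/cohort/.
"""

import argparse
from pathlib import Path

from apoetraj.colony import (apply_exclusions, load_colony_table,
                             summarize_cohort)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--colony", type=Path, default=Path("results/colony/colony.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    mice, report = load_colony_table(args.colony)
    retained, report = apply_exclusions(mice, report=report)
    report.to_frame().to_csv(args.out / "exclusions.csv", index=False)
    report.to_json(args.out / "exclusions.json")
    summary = summarize_cohort(retained)
    summary.weight_by_age.to_csv(args.out / "weight_by_age.csv", index=False)
    summary.weight_by_age_sex.to_csv(args.out / "weight_by_age_sex.csv", index=False)

    reasons = {}
    for rs in report.mouse_reasons.values():
        for r in rs:
            reasons[r] = reasons.get(r, 0) + 1
    print(f"{len(mice)} mice loaded -> {summary.n_mice} retained "
          f"({summary.n_datapoints} datapoints); excluded by reason: {reasons}")
    print(f"sex: {summary.sex_pct['female']:.0f}% female / "
          f"{summary.sex_pct['male']:.0f}% male; genotypes: "
          + ", ".join(f"{k} {v:.0f}%" for k, v in summary.genotype_pct.items()))
    print(f">{5} weighings: {summary.n_more_than_5} mice; "
          f">{10}: {summary.n_more_than_10} mice")
    print(f"report in {args.out}")


if __name__ == "__main__":
    main()
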