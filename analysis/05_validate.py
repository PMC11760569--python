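#!/usr/bin/env python
"""Validate the discovered trajectories with independent measurements.

Runs the post-hoc battery on the grouped cohort: Kaplan-Meier survival per
trajectory with the K-sample log-rank test (sacrificed mice excluded),
chi-square composition tests of sex and genotype across groups, and Welch
t-tests on the plasma-biomarker and body-composition panels.  Writes a JSON
summary under results/validation/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from apoetraj.colony import apply_exclusions, load_colony_table
from apoetraj.validation import (compare_cs_across_states, contingency_chisq,
                                 km_estimate, logrank_test, median_survival,
                                 survival_records)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--colony", type=Path, default=Path("results/colony/colony.csv"))
    ap.add_argument("--assignments", type=Path,
                    default=Path("results/trajectories/assignments.csv"))
    ap.add_argument("--groups", type=Path,
                    default=Path("results/trajectories/groups.csv"))
    ap.add_argument("--biomarkers", type=Path,
                    default=Path("results/colony/biomarkers.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/validation"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    mice, _ = load_colony_table(args.colony)
    retained, _ = apply_exclusions(mice)
    asg = pd.read_csv(args.assignments)
    ending = set(pd.read_csv(args.groups)["state"])
    group_map = {r.mouse_id: r.state for r in asg.itertuples()
                 if r.state in ending}
    out: dict = {}

    records = survival_records(retained, groups=group_map)
    by_group: dict = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    by_group = {k: v for k, v in sorted(by_group.items()) if len(v) >= 10}
    if len(by_group) >= 2 and sum(r.event for g in by_group.values() for r in g):
        chi2, df, p = logrank_test(list(by_group.values()))
        medians = {k: median_survival(km_estimate(v)) for k, v in by_group.items()}
        out["survival"] = {"n": sum(len(v) for v in by_group.values()),
                           "logrank_chi2": chi2, "df": df, "logrank_p": p,
                           "median_survival_months": medians}
        print(f"survival: log-rank chi2={chi2:.1f} (df={df}), p={p:.2e} "
              f"over {out['survival']['n']} mice")
        print("  median survival (months): "
              + ", ".join(f"{k}={v if v is None else round(v, 1)}"
                          for k, v in medians.items()))

    by_id = {m.mouse_id: m for m in retained}
    for attr in ("sex", "genotype"):
        comp = {}
        for mid, g in group_map.items():
            comp.setdefault(g, []).append(getattr(by_id[mid], attr))
        comp = {k: v for k, v in comp.items() if len(v) >= 5}
        if len(comp) >= 2:
            chi2, df, p, _ = contingency_chisq(comp)
            out[f"composition_{attr}"] = {"chi2": chi2, "df": df, "p": p}
            print(f"{attr} composition across trajectories: "
                  f"chi2={chi2:.1f} (df={df}), p={p:.2e}")

    if args.biomarkers.exists():
        bio = pd.read_csv(args.biomarkers)
        bio = bio[bio["mouse_id"].isin(group_map)].copy()
        bio["state"] = bio["mouse_id"].map(group_map)
        long = bio.melt(id_vars=["mouse_id", "state"],
                        value_vars=["abeta40", "abeta42"],
                        var_name="measurement", value_name="value")
        res = compare_cs_across_states(long)
        res.to_csv(args.out / "biomarker_tests.csv", index=False)
        sig = res[res["p"] < 0.05]
        print(f"biomarkers: {len(sig)}/{len(res.dropna(subset=['p']))} "
              f"pairwise Welch tests significant at 0.05")
        out["biomarkers"] = json.loads(res.to_json(orient="records"))

    with open(args.out / "validation.json", "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=1, default=str)
    print(f"summary in {args.out}")


if __name__ == "__main__":
    main()
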