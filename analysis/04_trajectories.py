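#!/usr/bin/env python
"""Derive weight trajectories from the fitted transition matrix.

Classifies states as starting/intermediate/ending (self-transition > 0.3),
assigns each mouse to the state occupied at its final visit, groups mice by
ending state, and computes per-group mean curves and percent weight change
from the 12-month anchor.  Writes assignments, group summaries and tidy
curves under results/trajectories/.
"""

import argparse
from pathlib import Path

import pandas as pd

from apoetraj.ahmm import FitResult
from apoetraj.colony import apply_exclusions, load_colony_table, to_observations
from apoetraj.trajectories import (assign_terminal_states, classify_states,
                                   group_by_trajectory, summarize_groups)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--colony", type=Path, default=Path("results/colony/colony.csv"))
    ap.add_argument("--fit", type=Path, default=Path("results/fit/fit.json"))
    ap.add_argument("--out", type=Path, default=Path("results/trajectories"))
    ap.add_argument("--threshold", type=float, default=0.3)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    mice, _ = load_colony_table(args.colony)
    retained, _ = apply_exclusions(mice)
    data = to_observations(retained)
    fit = FitResult.from_json(args.fit)

    cls = classify_states(fit.params.A, threshold=args.threshold,
                          labels=fit.state_labels)
    asg = assign_terminal_states(data, fit)
    groups, unassigned = group_by_trajectory(asg, cls, data)
    summary = summarize_groups(groups, data)

    asg.to_csv(args.out / "assignments.csv", index=False)
    summary.to_csv(args.out / "groups.csv", index=False)
    curves = pd.concat([g.curve.assign(state=g.label) for g in groups],
                       ignore_index=True) if groups else pd.DataFrame()
    curves.to_csv(args.out / "curves.csv", index=False)

    n = len(data)
    print(f"ending states ({len(cls.ending_states)} of {len(cls.labels)}): "
          + ", ".join(cls.ending_states))
    print(f"{n - len(unassigned)} mice grouped, {len(unassigned)} unassigned "
          f"({100 * len(unassigned) / n:.0f}%)")
    print(summary.to_string(index=False))
    print(f"tables in {args.out}")


if __name__ == "__main__":
    main()
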