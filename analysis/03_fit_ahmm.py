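#!/usr/bin/env python
"""Fit the 10-state autoregressive HMM to the analysis cohort.

Runs EM with random restarts on the preprocessed cohort, keeps the restart
with the highest log-likelihood, relabels states canonically by stationary
weight level (A = lightest), and writes the fitted model and transition
matrix under results/fit/.  Use --quick for a reduced smoke-scale run.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from apoetraj.ahmm import fit_with_restarts
from apoetraj.colony import apply_exclusions, load_colony_table, to_observations


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--colony", type=Path, default=Path("results/colony/colony.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/fit"))
    ap.add_argument("--n-states", type=int, default=10)
    ap.add_argument("--n-restarts", type=int, default=10)
    ap.add_argument("--n-iters", type=int, default=1500)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--quick", action="store_true",
                    help="3 restarts x 150 iterations")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    if args.quick:
        args.n_restarts, args.n_iters = 3, 150

    mice, _ = load_colony_table(args.colony)
    retained, _ = apply_exclusions(mice)
    data = to_observations(retained)
    fit = fit_with_restarts(data, n_states=args.n_states, n_iters=args.n_iters,
                            n_restarts=args.n_restarts, master_seed=args.seed)
    fit.to_json(args.out / "fit.json")
    labels = fit.state_labels
    pd.DataFrame(fit.params.A, index=labels, columns=labels).to_csv(
        args.out / "transition_matrix.csv")

    lls = [f"{x:.0f}" for x in fit.restart_logliks if np.isfinite(x)]
    print(f"fitted {args.n_states} states on {len(data)} mice "
          f"({sum(len(d) for d in data)} visits)")
    print(f"restart log-likelihoods: {', '.join(lls)}; "
          f"kept restart {fit.best_restart} (LL {fit.log_likelihood:.0f})")
    print("state weight levels (g): "
          + ", ".join(f"{l}={v:.1f}" for l, v in
                      zip(labels, fit.params.stationary_weight_level())))
    print(f"model in {args.out}")


if __name__ == "__main__":
    main()
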