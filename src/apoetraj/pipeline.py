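"""End-to-end pipeline: preprocess -> fit -> classify -> group -> validate.

A single :class:`PipelineConfig` (YAML-serializable) governs every stage and
every source of randomness via one master seed; re-running with an identical
config and inputs reproduces identical artifacts.  Each run writes, under the
output directory: the exclusion report (CSV + JSON), the fitted model (JSON),
the transition matrix (CSV), per-mouse group assignments (CSV), per-group
weight curves (CSV), validation summaries (JSON), a config snapshot stamped
with its hash, and a structured run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import trajectories as traj_mod
from . import validation as val_mod
from .ahmm import FitResult, fit_with_restarts
from .colony import PreprocessConfig, apply_exclusions, load_colony_table, to_observations

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    colony_table: str = ""
    biomarker_table: str | None = None
    body_composition_table: str | None = None
    output_dir: str = "results/run"
    # preprocessing
    min_age_months: float = 5.0
    min_points: int = 3
    max_monthly_loss: float = 0.20
    exclude_breeders: bool = True
    # model
    n_states: int = 10
    n_iters: int = 1500
    n_restarts: int = 10
    seed: int = 0
    ending_threshold: float = 0.3
    decode_method: str = "posterior"
    # curves / phenotypes
    curve_min_n: int = 3
    curve_bin_width: float = 1.0
    ref_age_months: float = 12.0
    # report toggles
    write_plots: bool = False

    def validate(self) -> None:
        if self.n_states < 1:
            raise ConfigError("n_states must be >= 1")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        if self.n_iters < 1:
            raise ConfigError("n_iters must be >= 1")
        if not 0 < self.ending_threshold < 1:
            raise ConfigError("ending_threshold must be in (0, 1)")
        if self.decode_method not in {"posterior", "viterbi"}:
            raise ConfigError("decode_method must be 'posterior' or 'viterbi'")
        if self.min_points < 1 or self.min_age_months < 0 \
                or not 0 < self.max_monthly_loss < 1:
            raise ConfigError("preprocessing thresholds out of range")
        if self.curve_min_n < 1 or self.curve_bin_width <= 0:
            raise ConfigError("curve settings out of range")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunArtifacts:
    output_dir: Path
    config: PipelineConfig
    n_input_mice: int = 0
    n_retained_mice: int = 0
    fit: FitResult | None = None
    classification: object = None
    groups: list = field(default_factory=list)
    unassigned: list = field(default_factory=list)
    group_summary: pd.DataFrame | None = None
    validation: dict = field(default_factory=dict)


def _write_transition_csv(fit: FitResult, path) -> None:
    labels = fit.state_labels
    pd.DataFrame(fit.params.A, index=labels, columns=labels).to_csv(path)


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    """Execute all stages in order, persisting artifacts as each completes."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("apoetraj")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    art = RunArtifacts(output_dir=out, config=config)
    try:
        config.to_yaml(out / "config_snapshot.yaml")
        (out / "config_hash.txt").write_text(config.digest() + "\n")
        logger.info("run started; config hash %s seed %d", config.digest(), config.seed)

        # --- preprocess -----------------------------------------------------
        mice, report = load_colony_table(config.colony_table)
        art.n_input_mice = len(mice)
        rules = PreprocessConfig(
            min_age_months=config.min_age_months, min_points=config.min_points,
            max_monthly_loss=config.max_monthly_loss,
            exclude_breeders=config.exclude_breeders)
        retained, report = apply_exclusions(mice, rules, report)
        art.n_retained_mice = len(retained)
        report.to_frame().to_csv(out / "exclusions.csv", index=False)
        report.to_json(out / "exclusions.json")
        logger.info("preprocess: %d in -> %d retained", len(mice), len(retained))
        if not retained:
            raise RuntimeError("stage preprocess: no mice retained")

        # --- fit ------------------------------------------------------------
        data = to_observations(retained)
        fit = fit_with_restarts(
            data, n_states=config.n_states, n_iters=config.n_iters,
            n_restarts=config.n_restarts, master_seed=config.seed)
        art.fit = fit
        fit.to_json(out / "fit.json")
        _write_transition_csv(fit, out / "transition_matrix.csv")
        logger.info("fit: best restart %d loglik %.2f", fit.best_restart,
                    fit.log_likelihood)

        # --- classify + group ----------------------------------------------
        classification = traj_mod.classify_states(
            fit.params.A, threshold=config.ending_threshold,
            labels=fit.state_labels)
        art.classification = classification
        assignments = traj_mod.assign_terminal_states(
            data, fit, method=config.decode_method)
        groups, unassigned = traj_mod.group_by_trajectory(
            assignments, classification, data)
        art.groups, art.unassigned = groups, unassigned
        assignments.to_csv(out / "assignments.csv", index=False)
        summary = traj_mod.summarize_groups(
            groups, data, ref_age=config.ref_age_months, min_n=config.curve_min_n)
        art.group_summary = summary
        summary.to_csv(out / "groups.csv", index=False)
        curves = pd.concat(
            [g.curve.assign(state=g.label) for g in groups], ignore_index=True
        ) if groups else pd.DataFrame(columns=["age_bin", "n", "mean", "sd", "state"])
        curves.to_csv(out / "curves.csv", index=False)
        logger.info("trajectories: %d ending states, %d grouped, %d unassigned",
                    len(classification.ending_states),
                    sum(g.n for g in groups), len(unassigned))

        # --- validate -------------------------------------------------------
        validation = {}
        group_map = {m: g.label for g in groups for m in g.mouse_ids}
        records = val_mod.survival_records(retained, groups=group_map)
        by_group = {}
        for r in records:
            by_group.setdefault(r.group, []).append(r)
        by_group = {k: v for k, v in by_group.items() if len(v) >= 2}
        if len(by_group) >= 2 and sum(r.event for r in records) > 0:
            chi2, dfree, p = val_mod.logrank_test(list(by_group.values()))
            medians = {}
            for k, recs in by_group.items():
                km = val_mod.km_estimate(recs)
                medians[k] = val_mod.median_survival(km)
            validation["survival"] = {
                "n": len(records), "logrank_chi2": chi2, "df": dfree,
                "logrank_p": p, "median_survival_months": medians,
            }
        by_id = {m.mouse_id: m for m in retained}
        for attr in ("sex", "genotype"):
            comp = {g.label: [getattr(by_id[m], attr) for m in g.mouse_ids]
                    for g in groups if g.n > 0}
            if len(comp) >= 2:
                try:
                    chi2, dfree, p, _ = val_mod.contingency_chisq(comp)
                    validation[f"composition_{attr}"] = {
                        "chi2": chi2, "df": dfree, "p": p}
                except ValueError:
                    pass
        for name, tbl_path, cols in (
                ("biomarkers", config.biomarker_table, ("abeta40", "abeta42")),
                ("body_composition", config.body_composition_table,
                 ("fat_g", "lean_g"))):
            if tbl_path is None:
                continue
            tbl = pd.read_csv(tbl_path)
            tbl = tbl[tbl["mouse_id"].isin(group_map)]
            tbl["group"] = tbl["mouse_id"].map(group_map)
            long = tbl.melt(id_vars=["mouse_id", "group"], value_vars=list(cols),
                            var_name="measurement", value_name="value")
            res = val_mod.compare_cs_across_states(
                long, state_col="group")
            validation[name] = json.loads(res.to_json(orient="records"))
        with open(out / "validation.json", "w", encoding="utf-8") as fh:
            json.dump(validation, fh, indent=1, default=str)
        art.validation = validation
        logger.info("validation complete: %s", sorted(validation))

        if config.write_plots:
            _write_plots(art, out)
        logger.info("run finished")
    except Exception as exc:
        logger.error("pipeline halted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return art


def _write_plots(art: RunArtifacts, out: Path) -> None:
    """Basic per-figure exports: cohort curve, group curves, survival steps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for g in art.groups:
        if g.curve is None or g.curve.empty:
            continue
        ax.errorbar(g.curve["age_bin"], g.curve["mean"], yerr=g.curve["sd"],
                    label=f"{g.label} (n={g.n})", capsize=2)
    ax.set_xlabel("age (months)")
    ax.set_ylabel("weight (g)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "trajectory_curves.png", dpi=120)
    plt.close(fig)
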