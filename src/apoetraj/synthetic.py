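"""Synthetic aging-colony generator with known ground truth.

Emulates the statistical structure the trajectory analysis assumes: a colony
of ~1,200 humanized-APOE mice (45% female / 55% male; genotypes E3/3, E3/4,
E4/4 at 30/28/42%), weighed roughly monthly at irregular intervals between 5
and 28 months of age, whose weight dynamics follow a state-dependent AR(1)
process with a male offset.  Hidden states are "archetypes" — attractors of
the AR process at distinct weight levels (deep-loss, loss, stable, heavy,
gain) — coupled to genotype through the initial-state distribution (the gain
archetype enriched for E4/4 carriers), to mortality through a per-state
constant monthly hazard, and to plasma-biomarker means.

Every draw flows from the single config seed, so identical configs produce
byte-identical tables.  The generator writes the same long-format colony
table the loader reads, which closes the round-trip test surface, and emits
a :class:`GroundTruth` aligned row-for-row with the colony table so that
parameter- and trajectory-recovery can be scored exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ahmm import AHMMParams, GENOTYPE_LEVELS, SEX_LEVELS

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44


class ConfigError(ValueError):
    """A TrueColonyConfig field violates its invariants."""


@dataclass
class StateArchetype:
    """Generative parameters of one hidden state.

    ``weight_intercept``/``male_offset`` are the AR regression intercepts in
    grams (the female attractor level is intercept/(1-ar_slope)); the age
    window (months) sets the state's age-emission Gaussian; ``hazard_per_month``
    is the constant death hazard while occupying the state; the biomarker mean
    and sd parameterize the state's plasma Abeta40-like emission.
    """

    weight_intercept: float
    male_offset: float
    ar_slope: float
    weight_sd: float
    age_window: tuple = (5.0, 28.0)
    hazard_per_month: float = 0.01
    biomarker_mean: float = 60.0
    biomarker_sd: float = 12.0

    @property
    def attractor(self) -> float:
        return self.weight_intercept / (1.0 - self.ar_slope)


def _archetype_from_level(level, male_level_offset, phi, sd, age_window,
                          hazard, bm_mean, bm_sd) -> StateArchetype:
    """Build an archetype from its stationary (attractor) weight level."""
    return StateArchetype(
        weight_intercept=level * (1.0 - phi),
        male_offset=male_level_offset * (1.0 - phi),
        ar_slope=phi,
        weight_sd=sd,
        age_window=age_window,
        hazard_per_month=hazard,
        biomarker_mean=bm_mean,
        biomarker_sd=bm_sd,
    )


def default_archetypes() -> list[StateArchetype]:
    """Five archetypes emulating the study's loss/stable/gain phenotypes.

    Ordered by attractor weight: deep-loss (18 g), loss (23 g), stable (29 g),
    heavy (36 g), gain (48 g).  The gain state carries the highest mortality
    hazard and biomarker mean; the stable state the lowest hazard.
    """
    return [
        _archetype_from_level(18.0, 4.0, 0.55, 1.2, (16.0, 28.0), 0.030, 62.0, 12.0),
        _archetype_from_level(23.0, 4.0, 0.55, 1.2, (13.0, 28.0), 0.020, 60.0, 12.0),
        _archetype_from_level(29.0, 5.0, 0.55, 1.3, (5.0, 28.0), 0.012, 65.0, 12.0),
        _archetype_from_level(36.0, 5.0, 0.55, 1.5, (5.0, 26.0), 0.018, 75.0, 12.0),
        _archetype_from_level(48.0, 5.0, 0.60, 1.8, (10.0, 28.0), 0.045, 110.0, 15.0),
    ]


def default_transition_matrix() -> np.ndarray:
    """Sticky 5-state matrix with flow from stable/heavy toward loss and gain."""
    return np.array([
        [0.950, 0.030, 0.010, 0.007, 0.003],   # deep loss (near absorbing)
        [0.060, 0.900, 0.020, 0.015, 0.005],   # loss
        [0.015, 0.035, 0.870, 0.060, 0.020],   # stable
        [0.005, 0.015, 0.060, 0.850, 0.070],   # heavy
        [0.003, 0.004, 0.013, 0.060, 0.920],   # gain (near absorbing)
    ])


def default_init_dist_by_genotype() -> np.ndarray:
    """Initial-state distribution per genotype; gain enriched for E4/4."""
    return np.array([
        [0.02, 0.08, 0.60, 0.25, 0.05],   # E3/3
        [0.02, 0.12, 0.58, 0.23, 0.05],   # E3/4
        [0.02, 0.06, 0.42, 0.35, 0.15],   # E4/4
    ])


@dataclass
class TrueColonyConfig:
    """Ground-truth configuration of a simulated colony."""

    n_mice: int = 1196
    n_states: int = 5
    sex_probs: tuple = (0.45, 0.55)                      # female, male
    genotype_probs: tuple = (0.30, 0.28, 0.42)           # E3/3, E3/4, E4/4
    state_archetypes: list = field(default_factory=default_archetypes)
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    init_dist_by_genotype: np.ndarray = field(default_factory=default_init_dist_by_genotype)
    visit_spacing: tuple = (1.0, 0.25)                   # mean, sd months
    min_gap_months: float = 0.5
    visit_window: tuple = (5.0, 28.0)                    # min, max age months
    first_visit_age_range: tuple = (5.0, 8.0)
    missing_visit_prob: float = 0.12
    breeder_prob: float = 0.05
    sacrifice_prob: float = 0.55
    sacrifice_age_range: tuple = (8.0, 26.0)
    biomarker_age_window: tuple = (12.0, 14.0)
    cohort_entry_window: tuple = ("2018-11-02", "2019-12-31")
    min_frac_three_visits: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.init_dist_by_genotype = np.asarray(self.init_dist_by_genotype, dtype=float)

    def validate(self) -> None:
        if self.n_mice <= 0:
            raise ConfigError("n_mice must be > 0")
        if self.n_states != len(self.state_archetypes):
            raise ConfigError("n_states must equal len(state_archetypes)")
        for name, v in (("sex_probs", self.sex_probs),
                        ("genotype_probs", self.genotype_probs)):
            v = np.asarray(v, dtype=float)
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-12:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        A = self.transition_matrix
        if A.shape != (self.n_states, self.n_states):
            raise ConfigError("transition_matrix shape must be (n_states, n_states)")
        if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigError("transition_matrix rows must sum to 1 within 1e-12")
        D = self.init_dist_by_genotype
        if D.shape != (3, self.n_states):
            raise ConfigError("init_dist_by_genotype must be (3, n_states)")
        if np.any(D < 0) or np.any(np.abs(D.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigError("init_dist_by_genotype rows must sum to 1 within 1e-12")
        lo, hi = self.visit_window
        if lo < 0 or lo >= hi:
            raise ConfigError("visit_window must satisfy 0 <= min < max")
        for a in self.state_archetypes:
            if a.weight_sd <= 0:
                raise ConfigError("weight_sd must be > 0")
            if a.hazard_per_month < 0:
                raise ConfigError("hazard_per_month must be >= 0")
        if not 0.0 <= self.missing_visit_prob <= 1.0:
            raise ConfigError("missing_visit_prob must be a probability")


@dataclass
class GroundTruth:
    """Generative truth aligned row-for-row with the simulated colony table."""

    params: AHMMParams
    mouse_ids: list
    sex: dict                   # mouse_id -> 0/1
    genotype: dict              # mouse_id -> 0/1/2
    state_paths: dict           # mouse_id -> list of true states, one per recorded visit
    visit_ages: dict            # mouse_id -> list of ages (months) per recorded visit
    terminal_state: dict        # mouse_id -> last path element
    death_age: dict             # mouse_id -> age in months, or None if censored
    death_cause: dict           # mouse_id -> 'natural' | 'sacrificed' | None

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "mouse_ids": self.mouse_ids,
            "sex": self.sex,
            "genotype": self.genotype,
            "state_paths": self.state_paths,
            "visit_ages": self.visit_ages,
            "terminal_state": self.terminal_state,
            "death_age": self.death_age,
            "death_cause": self.death_cause,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


@dataclass
class PostHocTables:
    """Simulated validation tables: plasma biomarkers and body composition."""

    biomarkers: pd.DataFrame    # mouse_id, age_months, abeta40, abeta42, true_state
    body_composition: pd.DataFrame  # mouse_id, age_months, fat_g, lean_g, free_water_g, true_state


def generate_true_params(config: TrueColonyConfig) -> AHMMParams:
    """Assemble the AHMMParams implied by a colony config (deterministic).

    Emission families match the fitted model exactly: per-state age Gaussian
    from the archetype's age window (mean at the midpoint, sd a quarter of the
    range), sex categorical equal to the colony sex distribution, genotype
    categorical from Bayes inversion of the genotype-coupled initial-state
    distribution, AR weight regression from the archetype, and a first-visit
    Gaussian at the archetype's stationary AR marginal.
    """
    config.validate()
    arcs = config.state_archetypes
    N = config.n_states
    geno_p = np.asarray(config.genotype_probs, dtype=float)
    init_by_geno = config.init_dist_by_genotype
    pi = geno_p @ init_by_geno
    pi = pi / pi.sum()
    joint = geno_p[:, None] * init_by_geno       # (3, N)
    geno_probs = (joint / joint.sum(axis=0, keepdims=True)).T

    age_mean = np.array([(a.age_window[0] + a.age_window[1]) / 2.0 for a in arcs])
    age_var = np.array([max(((a.age_window[1] - a.age_window[0]) / 4.0) ** 2, 1e-2)
                        for a in arcs])
    phi = np.array([a.ar_slope for a in arcs])
    alpha = np.array([a.weight_intercept for a in arcs])
    delta = np.array([a.male_offset for a in arcs])
    sd = np.array([a.weight_sd for a in arcs])
    stable = np.abs(phi) < 1.0
    w0_mean = np.where(stable, alpha / (1.0 - phi), alpha)
    w0_male = np.where(stable, delta / (1.0 - phi), delta)
    w0_var = np.where(stable, sd ** 2 / (1.0 - phi ** 2), sd ** 2)

    params = AHMMParams(
        pi=pi,
        A=config.transition_matrix.copy(),
        age_mean=age_mean,
        age_var=age_var,
        sex_probs=np.tile(np.asarray(config.sex_probs, dtype=float), (N, 1)),
        geno_probs=geno_probs,
        ar_intercept=alpha,
        ar_male=delta,
        ar_slope=phi,
        ar_var=sd ** 2,
        w0_intercept=w0_mean,
        w0_male=w0_male,
        w0_var=w0_var,
    )
    params.validate()
    return params


def _truncated_gauss(rng, mean, sd, lower):
    """Rejection-sampled Gaussian truncated below (falls back to lower bound)."""
    for _ in range(64):
        x = rng.normal(mean, sd)
        if x >= lower:
            return x
    return lower


def simulate_colony(
    params: AHMMParams, config: TrueColonyConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format colony table plus its aligned ground truth.

    One row per recorded visit: ages strictly increase within mouse, weights
    are positive, visits stop at simulated death (natural or sacrifice) or at
    the end of the observation window.  The first three visits are always
    recorded; later candidate visits are skipped with ``missing_visit_prob``
    (a skipped visit lengthens the gap and does not advance the state chain,
    so each recorded visit remains one Markov step).
    """
    config.validate()
    params.validate()
    rng = np.random.default_rng(config.seed)
    arcs = config.state_archetypes
    hazards = np.array([a.hazard_per_month for a in arcs])
    A = config.transition_matrix
    lo_win, hi_win = config.visit_window
    entry_lo = pd.Timestamp(config.cohort_entry_window[0])
    entry_hi = pd.Timestamp(config.cohort_entry_window[1])
    entry_days = int((entry_hi - entry_lo).days)

    rows = []
    ids, sex_map, geno_map = [], {}, {}
    paths, age_map, term, death_age, death_cause = {}, {}, {}, {}, {}

    for m in range(config.n_mice):
        mid = f"M{m:05d}"
        sex = int(rng.random() < config.sex_probs[1])
        geno = int(rng.choice(3, p=np.asarray(config.genotype_probs, dtype=float)))
        male = float(sex)
        is_breeder = bool(rng.random() < config.breeder_prob)
        birth = entry_lo + pd.Timedelta(days=int(rng.integers(0, entry_days + 1)))

        sac_age = None
        if rng.random() < config.sacrifice_prob:
            sac_age = float(rng.uniform(*config.sacrifice_age_range))

        state = int(rng.choice(config.n_states, p=config.init_dist_by_genotype[geno]))
        age = float(rng.uniform(*config.first_visit_age_range))
        w = float(rng.normal(params.w0_intercept[state] + params.w0_male[state] * male,
                             np.sqrt(params.w0_var[state])))
        w = max(w, 1.0)

        ages_rec, weights_rec, states_rec = [age], [w], [state]
        d_age, d_cause = None, None
        n_recorded = 1
        while True:
            gap = _truncated_gauss(rng, config.visit_spacing[0],
                                   config.visit_spacing[1], config.min_gap_months)
            # death hazard of the currently occupied state over this gap
            h = hazards[state]
            if h > 0:
                t_death = rng.exponential(1.0 / h)
                if t_death < gap:
                    d_age, d_cause = age + t_death, "natural"
                    break
            next_age = age + gap
            if sac_age is not None and next_age > sac_age:
                d_age, d_cause = sac_age, "sacrificed"
                break
            if next_age > hi_win:
                break
            age = next_age
            if n_recorded >= 3 and rng.random() < config.missing_visit_prob:
                continue  # skipped weighing: gap accumulates, no Markov step
            state = int(rng.choice(config.n_states, p=A[state]))
            w = float(rng.normal(params.ar_intercept[state]
                                 + params.ar_male[state] * male
                                 + params.ar_slope[state] * w,
                                 np.sqrt(params.ar_var[state])))
            w = max(w, 1.0)
            ages_rec.append(age)
            weights_rec.append(w)
            states_rec.append(state)
            n_recorded += 1

        death_date = (birth + pd.Timedelta(days=round(d_age * DAYS_PER_MONTH))
                      if d_age is not None else pd.NaT)
        for a, wt in zip(ages_rec, weights_rec):
            rows.append({
                "mouse_id": mid,
                "sex": SEX_LEVELS[sex],
                "genotype": GENOTYPE_LEVELS[geno],
                "birth_date": birth,
                "death_date": death_date,
                "death_cause": d_cause,
                "is_breeder": is_breeder,
                "measurement_date": birth + pd.Timedelta(days=round(a * DAYS_PER_MONTH)),
                "weight_g": round(wt, 2),
            })
        ids.append(mid)
        sex_map[mid] = sex
        geno_map[mid] = geno
        paths[mid] = states_rec
        age_map[mid] = ages_rec
        term[mid] = states_rec[-1]
        death_age[mid] = d_age
        death_cause[mid] = d_cause

    table = pd.DataFrame(rows)
    truth = GroundTruth(
        params=params, mouse_ids=ids, sex=sex_map, genotype=geno_map,
        state_paths=paths, visit_ages=age_map, terminal_state=term,
        death_age=death_age, death_cause=death_cause,
    )
    frac3 = np.mean([len(paths[i]) >= 3 for i in ids])
    if frac3 < config.min_frac_three_visits:
        logger.warning("only %.1f%% of mice have >=3 visits (configured floor %.1f%%)",
                       100 * frac3, 100 * config.min_frac_three_visits)
    return table, truth


def simulate_posthoc_measures(
    truth: GroundTruth, config: TrueColonyConfig
) -> PostHocTables:
    """Draw one biomarker pair and one body-composition triple per eligible mouse.

    A mouse is eligible if it has a recorded visit inside the biomarker age
    window (default 12-14 months); values are emitted from the true state
    occupied at that visit.  The Abeta42-like channel is a scaled copy of the
    Abeta40-like channel's state mean (factor 0.22), mirroring the smaller
    physiological concentrations of the longer peptide.  Body fat fraction
    rises with the state's attractor weight, so the gain archetype has the
    highest adipose index by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.biomarker_age_window
    arcs = config.state_archetypes
    bio_rows, comp_rows = [], []
    for mid in truth.mouse_ids:
        ages = np.asarray(truth.visit_ages[mid])
        in_win = np.where((ages >= lo) & (ages <= hi))[0]
        if len(in_win) == 0:
            continue
        v = int(in_win[0])
        s = truth.state_paths[mid][v]
        a = arcs[s]
        ab40 = rng.normal(a.biomarker_mean, a.biomarker_sd)
        ab42 = rng.normal(a.biomarker_mean * 0.22, a.biomarker_sd * 0.22)
        bio_rows.append({"mouse_id": mid, "age_months": float(ages[v]),
                         "abeta40": ab40, "abeta42": ab42, "true_state": s})
        level = a.attractor
        fat_pct = float(np.clip(8.0 + 0.8 * (level - 18.0), 5.0, 55.0))
        total = level + 5.0 * truth.sex[mid]
        fat = max(rng.normal(total * fat_pct / 100.0, 0.06 * total), 0.0)
        water = max(rng.normal(0.3, 0.05), 0.0)
        lean = max(total - fat - water, 0.0)
        comp_rows.append({"mouse_id": mid, "age_months": float(ages[v]),
                          "fat_g": fat, "lean_g": lean, "free_water_g": water,
                          "true_state": s})
    if not bio_rows:
        logger.warning("biomarker age window (%s, %s) selected no mice", lo, hi)
    bio = pd.DataFrame(bio_rows, columns=["mouse_id", "age_months", "abeta40",
                                          "abeta42", "true_state"])
    comp = pd.DataFrame(comp_rows, columns=["mouse_id", "age_months", "fat_g",
                                            "lean_g", "free_water_g", "true_state"])
    return PostHocTables(biomarkers=bio, body_composition=comp)


def uniform_sticky_matrix(n_states: int, stay: float = 0.85) -> np.ndarray:
    """Transition matrix with ``stay`` on the diagonal, rest spread uniformly."""
    if n_states == 1:
        return np.array([[1.0]])
    off = (1.0 - stay) / (n_states - 1)
    A = np.full((n_states, n_states), off)
    np.fill_diagonal(A, stay)
    return A


def make_config(archetypes: list[StateArchetype], *, stay: float = 0.85,
                **overrides) -> TrueColonyConfig:
    """Config for custom archetypes: sticky transitions, uncoupled genotypes."""
    n = len(archetypes)
    cfg = TrueColonyConfig(
        n_states=n,
        state_archetypes=archetypes,
        transition_matrix=overrides.pop("transition_matrix",
                                        uniform_sticky_matrix(n, stay)),
        init_dist_by_genotype=overrides.pop(
            "init_dist_by_genotype", np.tile(np.full(n, 1.0 / n), (3, 1))),
        **overrides,
    )
    return cfg


def three_state_config(n_mice: int = 300, seed: int = 0,
                       **overrides) -> TrueColonyConfig:
    """Well-separated 3-state colony (~10-12 visits/mouse) for recovery tests.

    Low AR slopes keep the intercepts strongly identified; zero hazard and
    no sacrifice keep sequences full length.
    """
    # identical age windows: state occupancy is age-independent under the
    # sticky chain, so the generative age emission must not separate states
    arcs = [
        _archetype_from_level(18.0, 4.0, 0.20, 1.2, (5.0, 18.0), 0.0, 55.0, 10.0),
        _archetype_from_level(30.0, 5.0, 0.30, 1.2, (5.0, 18.0), 0.0, 70.0, 10.0),
        _archetype_from_level(44.0, 5.0, 0.25, 1.4, (5.0, 18.0), 0.0, 105.0, 12.0),
    ]
    defaults = dict(visit_window=(5.0, 18.0), sacrifice_prob=0.0,
                    breeder_prob=0.0, missing_visit_prob=0.05)
    defaults.update(overrides)
    return make_config(arcs, stay=0.85, n_mice=n_mice, seed=seed, **defaults)


def five_state_config(n_mice: int = 600, seed: int = 0,
                      **overrides) -> TrueColonyConfig:
    """Five well-separated archetypes under a symmetric sticky chain.

    With uniform initial states and an exchangeable sticky transition matrix,
    state occupancy is independent of age at every visit, so the hidden
    structure is identified purely by the weight dynamics; all diagonals sit
    at 0.9, well above the 0.3 ending-state threshold.  Used for end-to-end
    trajectory-recovery checks.
    """
    # separation is deliberately strong relative to the within-state sd:
    # any solution that merges weight levels (e.g. to buy sex-pure states,
    # which earn the categorical-emission entropy each visit) must absorb
    # frequent 8 g level jumps and loses more likelihood than it gains
    arcs = [
        _archetype_from_level(18.0, 2.0, 0.35, 1.0, (5.0, 20.0), 0.0, 55.0, 10.0),
        _archetype_from_level(26.0, 2.0, 0.35, 1.0, (5.0, 20.0), 0.0, 62.0, 10.0),
        _archetype_from_level(34.0, 2.5, 0.35, 1.0, (5.0, 20.0), 0.0, 70.0, 10.0),
        _archetype_from_level(42.0, 2.5, 0.35, 1.0, (5.0, 20.0), 0.0, 85.0, 10.0),
        _archetype_from_level(50.0, 2.5, 0.35, 1.2, (5.0, 20.0), 0.0, 110.0, 12.0),
    ]
    defaults = dict(visit_window=(5.0, 20.0), sacrifice_prob=0.0,
                    breeder_prob=0.0, missing_visit_prob=0.05)
    defaults.update(overrides)
    return make_config(arcs, stay=0.80, n_mice=n_mice, seed=seed, **defaults)


def truth_observations(table: pd.DataFrame, truth: GroundTruth):
    """ObservationSequences straight from a simulated table (no preprocessing)."""
    from .ahmm import ObservationSequence

    by_id = {m: g for m, g in table.groupby("mouse_id")}
    out = []
    for mid in truth.mouse_ids:
        out.append(ObservationSequence(
            mouse_id=mid, sex=truth.sex[mid], genotype=truth.genotype[mid],
            ages=np.asarray(truth.visit_ages[mid]),
            weights=by_id[mid]["weight_g"].to_numpy(),
        ))
    return out


def write_colony_csv(table: pd.DataFrame, path) -> None:
    """Write the colony table as UTF-8 CSV with ISO-8601 dates."""
    out = table.copy()
    for col in ("birth_date", "death_date", "measurement_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8")


def write_colony_xlsx(table: pd.DataFrame, path) -> None:
    """Write the colony table as XLSX (one row per measurement)."""
    table.to_excel(path, index=False)
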