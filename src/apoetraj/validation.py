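"""Post-hoc validation battery for discovered weight trajectories.

Four independent lines of evidence that trajectory groups differ:

* survival — Kaplan-Meier product-limit curves per group (time from birth to
  death, censoring at the last weight measurement; sacrificed mice excluded)
  compared by the K-sample log-rank test;
* composition — chi-square contingency tests of sex / genotype distributions
  across groups, overall and pairwise;
* biomarkers and body composition — Welch t-tests between groups on plasma
  Abeta concentrations and EchoMRI-style fat/lean masses, with the adipose
  index fat/(fat+lean+free water)*100;
* cross-sectional inference — Bayes-rule posterior over hidden states for a
  single (age, weight, sex, genotype) observation under the trained model,
  letting one-off physiological measurements be compared across inferred
  states.

The KM estimator and the log-rank test are implemented here directly; an
established survival library serves as an independent oracle in the test
suite only.  t-tests default to Welch (unequal variances); p-values are
reported unadjusted, with a Holm-adjusted column alongside for transparency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ahmm import (AHMMParams, FitResult, InferenceError, emission_logdensity)
from .colony import MouseSeries
from .trajectories import stationary_distribution

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecord:
    """Per-mouse time-to-event from birth, in months."""

    mouse_id: str
    time_months: float
    event: int            # 1 = death observed, 0 = censored
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(f"{self.mouse_id}: time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.mouse_id}: event must be 0 or 1")


def survival_records(
    mice: list[MouseSeries],
    groups: dict | None = None,
    exclude_sacrificed: bool = True,
) -> list[SurvivalRecord]:
    """Build survival records: death age when a natural death date exists,
    otherwise censoring at the last weight measurement.

    Mice flagged sacrificed are dropped entirely (their endpoint reflects
    experiment scheduling, not biology).  ``groups`` maps mouse_id -> group
    label; unmapped mice are skipped when a mapping is given.
    """
    out = []
    for m in mice:
        if exclude_sacrificed and (m.death_cause or "").startswith("sacrific"):
            continue
        if groups is not None and m.mouse_id not in groups:
            continue
        if not m.records:
            continue
        if m.death_date is not None and (m.death_cause or "natural") == "natural":
            t = (m.death_date - m.birth_date).days / 30.44
            event = 1
        else:
            t = m.records[-1].age_months
            event = 0
        if t <= 0:
            continue
        out.append(SurvivalRecord(m.mouse_id, float(t), event,
                                  groups.get(m.mouse_id) if groups else None))
    return out


def km_estimate(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a frame with one row per distinct event time: ``time``,
    ``n_at_risk``, ``n_events``, ``survival`` (the step value just after
    ``time``).  S(0) = 1 by construction; the curve is non-increasing.
    """
    if not records:
        raise ValueError("need at least one survival record")
    times = np.array([r.time_months for r in records])
    events = np.array([r.event for r in records])
    if events.sum() == 0:
        warnings.warn("no events observed; survival curve is flat at 1")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)
    rows = []
    s = 1.0
    i = 0
    while i < n:
        t = times[i]
        d = 0
        at_risk = n - i
        while i < n and times[i] == t:
            d += int(events[i])
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append({"time": float(t), "n_at_risk": int(at_risk),
                         "n_events": int(d), "survival": s})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def median_survival(km: pd.DataFrame) -> float | None:
    """Smallest time with S(t) <= 0.5; None when the curve never reaches 0.5."""
    hit = km[km["survival"] <= 0.5]
    if hit.empty:
        return None
    return float(hit.iloc[0]["time"])


def logrank_test(groups: list[list[SurvivalRecord]]):
    """K-sample log-rank test.

    Returns ``(chi2, df, p)`` with df = K-1.  Observed-minus-expected event
    counts are accumulated over distinct event times with the standard
    hypergeometric variance-covariance; the statistic is the quadratic form
    on the first K-1 groups.  Raises ValueError with fewer than 2 groups;
    returns ``(nan, df, nan)`` when no events occur.
    """
    K = len(groups)
    if K < 2:
        raise ValueError("log-rank needs at least 2 groups")
    times = np.concatenate([[r.time_months for r in g] for g in groups])
    events = np.concatenate([[r.event for r in g] for g in groups])
    gidx = np.concatenate([[k] * len(g) for k, g in enumerate(groups)]).astype(int)
    df = K - 1
    if events.sum() == 0:
        warnings.warn("no events in any group; log-rank not computable")
        return np.nan, df, np.nan

    event_times = np.unique(times[events == 1])
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(((times == t) & (events == 1)).sum())
        n_k = np.array([(at_risk & (gidx == k)).sum() for k in range(K)], dtype=float)
        d_k = np.array([((times == t) & (events == 1) & (gidx == k)).sum()
                        for k in range(K)], dtype=float)
        O += d_k
        E += d_t * n_k / n_t
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1)
            V += c * (np.diag(n_k / n_t) - np.outer(n_k, n_k) / n_t ** 2)
    z = (O - E)[:df]
    Vsub = V[:df, :df]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def contingency_chisq(
    groups: dict,
    pairwise: tuple | None = None,
):
    """Pearson chi-square on a groups x categories contingency table.

    ``groups`` maps group label -> list of category values (e.g. genotypes of
    its member mice).  ``pairwise=(label_a, label_b)`` restricts the test to
    the 2 x L subtable of those groups.  Empty rows/columns are collapsed with
    a warning.  Returns ``(chi2, df, p, expected)``.
    """
    if pairwise is not None:
        groups = {k: groups[k] for k in pairwise}
    rows = [{"group": g, "value": v} for g, vals in groups.items() for v in vals]
    table = pd.crosstab(pd.DataFrame(rows)["group"], pd.DataFrame(rows)["value"])
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("collapsing empty rows/columns in contingency table")
        table = table.loc[keep_r, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs >=2 non-empty rows and columns")
    chi2, p, df, expected = stats.chi2_contingency(table.values, correction=False)
    return float(chi2), int(df), float(p), pd.DataFrame(
        expected, index=table.index, columns=table.columns)


def welch_ttest(sample_a, sample_b, pooled: bool = False):
    """Two-sided t-test, Welch by default (``pooled=True`` for Student's).

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom under Welch.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def adipose_index(fat: float, lean: float, free_water: float) -> float:
    """Percent body fat: fat / (fat + lean + free water) * 100."""
    if fat < 0 or lean < 0 or free_water < 0:
        raise ValueError("masses must be >= 0")
    total = fat + lean + free_water
    if total <= 0:
        raise ValueError("total mass must be > 0")
    return 100.0 * fat / total


def infer_state_single_obs(
    fit: FitResult | AHMMParams,
    age: float,
    weight: float,
    sex: int,
    genotype: int,
    prior_mode: str = "stationary",
):
    """Posterior over hidden states for a single cross-sectional observation.

    ``posterior_i ∝ prior_i * emission(i; age, weight, sex, genotype)`` with
    the first-visit weight Gaussian (no autoregressive predecessor).  The
    prior is the stationary distribution of the fitted transition matrix
    (default) or the initial distribution (``prior_mode='initial'``).
    Returns ``(posterior, label)``.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    labels = (fit.state_labels if isinstance(fit, FitResult) and fit.state_labels
              else [chr(ord("A") + i) for i in range(params.n_states)])
    if prior_mode == "stationary":
        prior = stationary_distribution(params.A, pi=params.pi)
    elif prior_mode == "initial":
        prior = params.pi
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    N = params.n_states
    log_post = np.array([
        np.log(max(prior[i], 1e-300))
        + emission_logdensity(params, i, age, weight, None, sex, genotype)
        for i in range(N)
    ])
    log_post -= log_post.max()
    post = np.exp(log_post)
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise InferenceError("all-zero posterior for cross-sectional observation")
    post /= total
    return post, labels[int(np.argmax(post))]


def compare_cs_across_states(
    cs: pd.DataFrame,
    state_col: str = "state",
    value_col: str = "value",
    measurement_col: str = "measurement",
    pooled: bool = False,
) -> pd.DataFrame:
    """Pairwise Welch t-tests of cross-sectional values between inferred states.

    One row per (measurement, state pair): t, df, p, Holm-adjusted p (within
    measurement).  States with fewer than 2 records for a measurement are
    skipped with a note row (p = NaN).
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for meas, sub in cs.groupby(measurement_col):
        counts = sub.groupby(state_col)[value_col].count()
        usable = sorted(counts[counts >= 2].index)
        skipped = sorted(counts[counts < 2].index)
        for s in skipped:
            rows.append({"measurement": meas, "state_a": s, "state_b": None,
                         "t": np.nan, "df": np.nan, "p": np.nan,
                         "p_holm": np.nan, "note": "fewer than 2 records"})
        pvals, idx = [], []
        for i, a in enumerate(usable):
            for b in usable[i + 1:]:
                va = sub.loc[sub[state_col] == a, value_col].to_numpy()
                vb = sub.loc[sub[state_col] == b, value_col].to_numpy()
                if np.allclose(va.var(ddof=1) + vb.var(ddof=1), 0.0):
                    t, dfree, p = (0.0, float(len(va) + len(vb) - 2), 1.0) \
                        if np.isclose(va.mean(), vb.mean()) else (np.inf, np.nan, 0.0)
                else:
                    t, dfree, p = welch_ttest(va, vb, pooled=pooled)
                rows.append({"measurement": meas, "state_a": a, "state_b": b,
                             "t": t, "df": dfree, "p": p, "p_holm": np.nan,
                             "note": ""})
                pvals.append(p)
                idx.append(len(rows) - 1)
        if pvals:
            adj = multipletests(pvals, method="holm")[1]
            for j, r_i in enumerate(idx):
                rows[r_i]["p_holm"] = float(adj[j])
    return pd.DataFrame(rows, columns=["measurement", "state_a", "state_b",
                                       "t", "df", "p", "p_holm", "note"])
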