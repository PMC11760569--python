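"""Trajectory discovery from a fitted transition matrix.

A fitted transition matrix ``A = [a_ij]`` partitions states into roles:
*ending* states have a self-transition probability above a threshold (0.3 by
default) — once reached, a mouse tends to stay; among the remainder,
*starting* states are those with the least incoming probability mass and the
rest are *intermediate*.  Mice are assigned to the state occupied at their
final visit (argmax of the smoothed posterior by default, last Viterbi state
as an alternative); mice terminating in an ending state form that state's
trajectory group, the rest are left unassigned.  Group phenotypes are read
off the mean weight curve: percent change from the 12-month anchor (middle
age) to the end of the trajectory, with curve bins requiring at least 3 mice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ahmm import (FitResult, InferenceError, ObservationSequence,
                   forward_backward, viterbi)

logger = logging.getLogger(__name__)


class MatrixError(ValueError):
    pass


@dataclass
class StateClassification:
    labels: list                  # state labels in matrix order
    roles: dict                   # label -> 'starting' | 'intermediate' | 'ending'
    self_probs: dict              # label -> a_ii
    incoming_mass: dict           # label -> sum_{j != i} a_ji
    threshold: float

    @property
    def ending_states(self) -> list:
        return [s for s in self.labels if self.roles[s] == "ending"]


@dataclass
class TrajectoryGroup:
    label: str
    mouse_ids: list
    curve: pd.DataFrame = field(default_factory=pd.DataFrame)  # age_bin, n, mean, sd
    percent_change: float | None = None
    composition: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.mouse_ids)


def _check_stochastic(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MatrixError("transition matrix must be square")
    if np.any(A < -1e-12) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise MatrixError("transition matrix must be row-stochastic")
    return A


def classify_states(
    A: np.ndarray,
    threshold: float = 0.3,
    labels: list | None = None,
    starting_quantile: float = 0.34,
) -> StateClassification:
    """Partition states into ending / starting / intermediate roles.

    Ending: strict ``a_ii > threshold``.  Among non-ending states, those whose
    incoming probability mass (column sum excluding the diagonal) falls at or
    below the ``starting_quantile`` quantile are starting states; the rest are
    intermediate.
    """
    A = _check_stochastic(A)
    N = A.shape[0]
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(N)]
    diag = np.diag(A)
    incoming = A.sum(axis=0) - diag
    roles = {}
    non_ending = [i for i in range(N) if not diag[i] > threshold]
    if non_ending:
        cutoff = np.quantile([incoming[i] for i in non_ending], starting_quantile)
    for i in range(N):
        if diag[i] > threshold:
            roles[labels[i]] = "ending"
        elif incoming[i] <= cutoff:
            roles[labels[i]] = "starting"
        else:
            roles[labels[i]] = "intermediate"
    return StateClassification(
        labels=list(labels),
        roles=roles,
        self_probs={labels[i]: float(diag[i]) for i in range(N)},
        incoming_mass={labels[i]: float(incoming[i]) for i in range(N)},
        threshold=threshold,
    )


def assign_terminal_states(
    data: list[ObservationSequence],
    fit: FitResult,
    method: str = "posterior",
) -> pd.DataFrame:
    """Per-mouse terminal hidden state with assignment confidence.

    ``method='posterior'`` (default): argmax of the smoothed state posterior
    at the final visit, confidence = that posterior mass; ties resolve to the
    lower canonical label.  ``method='viterbi'``: last state of the most
    probable path, confidence = posterior mass of that state at the final
    visit.
    """
    if method not in {"posterior", "viterbi"}:
        raise ValueError(f"unknown method {method!r}")
    labels = fit.state_labels or [chr(ord("A") + i)
                                  for i in range(fit.params.n_states)]
    rows = []
    for seq in data:
        try:
            gamma, _, _ = forward_backward(seq, fit.params)
        except InferenceError as exc:
            raise InferenceError(f"inference failed for mouse {seq.mouse_id}: {exc}")
        last = gamma[-1]
        if method == "posterior":
            state = int(np.argmax(last))  # first max -> lower label on ties
        else:
            state = int(viterbi(seq, fit.params)[-1])
        rows.append({"mouse_id": seq.mouse_id, "state": labels[state],
                     "confidence": float(last[state])})
    return pd.DataFrame(rows, columns=["mouse_id", "state", "confidence"])


def group_by_trajectory(
    assignments: pd.DataFrame,
    classification: StateClassification,
    data: list[ObservationSequence] | None = None,
) -> tuple[list[TrajectoryGroup], list]:
    """Partition mice into per-ending-state groups and an unassigned set."""
    ending = set(classification.ending_states)
    groups = []
    unassigned = []
    by_id = {s.mouse_id: s for s in data} if data is not None else {}
    for label in classification.labels:
        if label not in ending:
            continue
        members = assignments.loc[assignments["state"] == label, "mouse_id"].tolist()
        if not members:
            continue
        comp = {}
        group = TrajectoryGroup(label=label, mouse_ids=members, composition=comp)
        if data is not None:
            group.curve = trajectory_curve([by_id[m] for m in members])
        groups.append(group)
    for _, row in assignments.iterrows():
        if row["state"] not in ending:
            unassigned.append(row["mouse_id"])
    return groups, unassigned


def trajectory_curve(
    members: list[ObservationSequence],
    min_n: int = 3,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Mean +/- sample SD of member weights per age bin.

    Bins are ``bin_width`` months wide, centered on integer multiples of the
    width (monthly cadence); bins holding fewer than ``min_n`` mice are
    omitted.
    """
    if not members:
        raise ValueError("group is empty")
    rows = [{"age_bin": round(a / bin_width) * bin_width, "weight": w,
             "mouse_id": s.mouse_id}
            for s in members for a, w in zip(s.ages, s.weights)]
    df = pd.DataFrame(rows)
    # one value per mouse per bin so heavily-sampled mice don't dominate
    df = df.groupby(["mouse_id", "age_bin"], as_index=False)["weight"].mean()
    out = (df.groupby("age_bin")["weight"]
           .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
           .reset_index())
    return out[out["n"] >= min_n].reset_index(drop=True)


def percent_weight_change(
    curve: pd.DataFrame,
    ref_age: float = 12.0,
    window: float = 1.0,
) -> float | None:
    """Signed percent change of the group mean weight from the reference age.

    ``100 * (m_end - m_ref) / m_ref`` where ``m_ref`` is the curve mean at the
    bin nearest ``ref_age`` (within ``+/- window`` months) and ``m_end`` the
    mean at the last bin.  Returns None (not computable) when no bin falls
    inside the window or nothing follows the reference bin.
    """
    if curve.empty:
        return None
    dist = (curve["age_bin"] - ref_age).abs()
    near = curve[dist <= window + 1e-9]
    if near.empty:
        logger.warning("no curve bin within +/-%s months of %s", window, ref_age)
        return None
    ref_row = near.loc[(near["age_bin"] - ref_age).abs().idxmin()]
    later = curve[curve["age_bin"] >= ref_row["age_bin"]]
    m_end = later.iloc[-1]["mean"]
    return float(100.0 * (m_end - ref_row["mean"]) / ref_row["mean"])


def stationary_distribution(
    A: np.ndarray,
    pi: np.ndarray | None = None,
    n_fallback_steps: int = 512,
) -> np.ndarray:
    """Stationary distribution nu with nu A = nu, sum(nu) = 1.

    Computed by eigen-decomposition of ``A^T``.  For reducible chains (the
    eigenvalue 1 is not simple) there is no unique stationary law; the
    function falls back to the expected long-run occupancy ``pi A^k`` with a
    warning (``pi`` uniform when not given).
    """
    A = _check_stochastic(A)
    N = A.shape[0]
    if pi is None:
        pi = np.full(N, 1.0 / N)
    vals, vecs = np.linalg.eig(A.T)
    close = np.where(np.abs(vals - 1.0) < 1e-9)[0]
    if len(close) != 1:
        warnings.warn("transition matrix is reducible; returning long-run "
                      "occupancy from the initial distribution")
        return pi @ np.linalg.matrix_power(A, n_fallback_steps)
    v = np.real(vecs[:, close[0]])
    v = np.abs(v)
    nu = v / v.sum()
    # polish to 1e-12 with a few power-iteration steps
    for _ in range(200):
        nxt = nu @ A
        if np.max(np.abs(nxt - nu)) < 1e-13:
            nu = nxt
            break
        nu = nxt
    return nu / nu.sum()


def summarize_groups(
    groups: list[TrajectoryGroup],
    data: list[ObservationSequence],
    ref_age: float = 12.0,
    min_n: int = 3,
) -> pd.DataFrame:
    """Tidy per-group summary: size, percent change, phenotype call."""
    by_id = {s.mouse_id: s for s in data}
    rows = []
    for g in groups:
        members = [by_id[m] for m in g.mouse_ids]
        curve = trajectory_curve(members, min_n=min_n)
        g.curve = curve
        g.percent_change = percent_weight_change(curve, ref_age=ref_age)
        pct = g.percent_change
        if pct is None:
            phenotype = "undetermined"
        elif pct <= -5.0:
            phenotype = "loss"
        elif pct >= 5.0:
            phenotype = "gain"
        else:
            phenotype = "stable"
        rows.append({"state": g.label, "n": g.n, "percent_change": pct,
                     "phenotype": phenotype})
    return pd.DataFrame(rows, columns=["state", "n", "percent_change", "phenotype"])
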