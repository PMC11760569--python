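"""Autoregressive hidden Markov model with mixed categorical/Gaussian emissions.

The model: each mouse contributes one variable-length sequence of visits.
A discrete hidden state ``H_t`` evolves as a first-order Markov chain with
row-stochastic transition matrix ``A = [a_ij]``.  At every visit the state
emits the observed tuple (age, sex, genotype, weight):

* age           ~ Normal(mu_age[i], var_age[i])
* sex           ~ Categorical(p_sex[i])          (re-emitted each visit)
* genotype      ~ Categorical(p_geno[i])         (re-emitted each visit)
* weight        ~ Normal(alpha[i] + delta[i]*[male] + phi[i]*w_prev, var_w[i])

i.e. the weight emission is first-order autoregressive on the previous
recorded weight with a state-specific male intercept offset (the sex-weight
interaction).  The first visit of a sequence, which has no predecessor, uses
a separate per-state Gaussian with its own male offset
(alpha0[i] + delta0[i]*[male], var_w0[i]).

Because the autoregressive parent of each weight is itself observed, exact
inference on this chain reduces to standard forward-backward / Viterbi with
the AR term folded into the per-visit emission density; this is the chain
specialization of junction-tree inference.  All recursions run in log space
and are batched over padded sequences, so fitting a ~1,000-mouse colony is
a vectorized numpy computation.

Fitting is maximum likelihood via EM (Baum-Welch): the E-step is the exact
forward-backward pass, the M-step has closed forms throughout (normalized
expected counts for ``pi`` and ``A``, responsibility-weighted frequencies for
the categoricals, weighted mean/variance for age, and responsibility-weighted
least squares on (1, [male], w_prev) for the AR weight regression).  Multiple
random restarts are run and the restart with the highest final log-likelihood
is kept; fitted states are then relabeled canonically (sorted by stationary
weight level) to the letters A, B, C, ...
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

SEX_LEVELS = ("female", "male")
GENOTYPE_LEVELS = ("E3/3", "E3/4", "E4/4")
STATE_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: variance floor for all Gaussian emissions, in squared units (g^2 / months^2)
VAR_FLOOR = 1e-3
#: probability floor applied before normalization of any categorical/transition row
PROB_FLOOR = 1e-12
#: log-density sentinel for zero-probability categories: log(PROB_FLOOR)
LOG_ZERO = float(np.log(PROB_FLOOR))


class ParameterError(ValueError):
    """A parameter set violates its invariants (named field in message)."""


class InferenceError(RuntimeError):
    """Inference failed, e.g. zero total likelihood at some visit."""


# ---------------------------------------------------------------------------
# parameters and observation containers
# ---------------------------------------------------------------------------


@dataclass
class AHMMParams:
    """Full parameter set of the autoregressive HMM.

    All fields are numpy arrays indexed by state (first axis).
    """

    pi: np.ndarray            # (N,) initial state distribution
    A: np.ndarray             # (N, N) row-stochastic transition matrix
    age_mean: np.ndarray      # (N,)
    age_var: np.ndarray       # (N,)
    sex_probs: np.ndarray     # (N, 2) female/male
    geno_probs: np.ndarray    # (N, 3) E3/3, E3/4, E4/4
    ar_intercept: np.ndarray  # (N,) alpha
    ar_male: np.ndarray       # (N,) delta, male offset in the AR regression
    ar_slope: np.ndarray      # (N,) phi
    ar_var: np.ndarray        # (N,)
    w0_intercept: np.ndarray  # (N,) alpha0, first-visit mean (female)
    w0_male: np.ndarray       # (N,) delta0
    w0_var: np.ndarray        # (N,)

    def __post_init__(self) -> None:
        for name in (
            "pi", "A", "age_mean", "age_var", "sex_probs", "geno_probs",
            "ar_intercept", "ar_male", "ar_slope", "ar_var",
            "w0_intercept", "w0_male", "w0_var",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    def validate(self) -> None:
        N = self.n_states
        if self.A.shape != (N, N):
            raise ParameterError(f"A must be ({N},{N}), got {self.A.shape}")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ParameterError("pi must sum to 1")
        if np.any(self.pi < -1e-12):
            raise ParameterError("pi must be non-negative")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-10):
            raise ParameterError("rows of A must sum to 1 within 1e-10")
        if np.any(self.A < -1e-12) or np.any(self.A > 1 + 1e-12):
            raise ParameterError("entries of A must lie in [0, 1]")
        if self.sex_probs.shape != (N, 2) or self.geno_probs.shape != (N, 3):
            raise ParameterError("sex_probs must be (N,2) and geno_probs (N,3)")
        if not np.allclose(self.sex_probs.sum(axis=1), 1.0, atol=1e-8):
            raise ParameterError("sex_probs rows must sum to 1")
        if not np.allclose(self.geno_probs.sum(axis=1), 1.0, atol=1e-8):
            raise ParameterError("geno_probs rows must sum to 1")
        for name in ("age_var", "ar_var", "w0_var"):
            if np.any(getattr(self, name) < VAR_FLOOR - 1e-12):
                raise ParameterError(f"{name} below variance floor {VAR_FLOOR}")
        for name in ("age_mean", "ar_intercept", "ar_male", "ar_slope",
                     "w0_intercept", "w0_male"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"{name} contains non-finite values")

    def permuted(self, order: np.ndarray) -> "AHMMParams":
        """Return a copy with states reordered so new state i = old state order[i]."""
        order = np.asarray(order)
        return AHMMParams(
            pi=self.pi[order],
            A=self.A[np.ix_(order, order)],
            age_mean=self.age_mean[order],
            age_var=self.age_var[order],
            sex_probs=self.sex_probs[order],
            geno_probs=self.geno_probs[order],
            ar_intercept=self.ar_intercept[order],
            ar_male=self.ar_male[order],
            ar_slope=self.ar_slope[order],
            ar_var=self.ar_var[order],
            w0_intercept=self.w0_intercept[order],
            w0_male=self.w0_male[order],
            w0_var=self.w0_var[order],
        )

    def stationary_weight_level(self) -> np.ndarray:
        """Per-state attractor of the weight AR process (female intercept).

        alpha/(1-phi) where the AR is stable (|phi|<1), alpha otherwise.
        Used only for canonical state ordering.
        """
        phi = self.ar_slope
        stable = np.abs(phi) < 1.0
        level = np.where(stable, self.ar_intercept / np.where(stable, 1.0 - phi, 1.0),
                         self.ar_intercept)
        return level

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist() for k in (
            "pi", "A", "age_mean", "age_var", "sex_probs", "geno_probs",
            "ar_intercept", "ar_male", "ar_slope", "ar_var",
            "w0_intercept", "w0_male", "w0_var")}

    @classmethod
    def from_dict(cls, d: dict) -> "AHMMParams":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class ObservationSequence:
    """One mouse's covariates plus its ordered (age, weight) measurements."""

    mouse_id: str
    sex: int       # 0 female, 1 male
    genotype: int  # 0 E3/3, 1 E3/4, 2 E4/4
    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.ages.shape != self.weights.shape:
            raise ValueError(f"{self.mouse_id}: ages and weights differ in length")
        if len(self.ages) >= 2 and not np.all(np.diff(self.ages) > 0):
            raise ValueError(f"{self.mouse_id}: ages must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ages)


@dataclass
class FitResult:
    """Outcome of a multi-restart EM fit, states canonically relabeled."""

    params: AHMMParams
    restart_logliks: list        # final log-likelihood per restart (nan if failed)
    traces: list                 # per-restart log-likelihood iteration traces
    best_restart: int
    master_seed: int
    state_labels: list = field(default_factory=list)  # canonical labels A.. per state index
    relabel_map: dict = field(default_factory=dict)   # raw fitted index -> canonical label

    @property
    def log_likelihood(self) -> float:
        return float(self.restart_logliks[self.best_restart])

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "restart_logliks": [None if not np.isfinite(x) else float(x)
                                for x in self.restart_logliks],
            "traces": [[float(v) for v in t] for t in self.traces],
            "best_restart": int(self.best_restart),
            "master_seed": int(self.master_seed),
            "state_labels": list(self.state_labels),
            "relabel_map": {str(k): v for k, v in self.relabel_map.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            params=AHMMParams.from_dict(d["params"]),
            restart_logliks=[np.nan if x is None else x for x in d["restart_logliks"]],
            traces=d["traces"],
            best_restart=d["best_restart"],
            master_seed=d["master_seed"],
            state_labels=d.get("state_labels", []),
            relabel_map={int(k): v for k, v in d.get("relabel_map", {}).items()},
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------


def _log_normal(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _log_cat(probs):
    return np.log(np.maximum(probs, PROB_FLOOR))


def emission_logdensity(
    params: AHMMParams,
    state: int,
    age: float,
    weight: float,
    prev_weight: float | None,
    sex: int,
    genotype: int,
) -> float:
    """Log emission density of one visit under one state.

    ``prev_weight=None`` marks a first visit (or a single cross-sectional
    observation), which uses the first-visit weight Gaussian.  Zero-probability
    categories contribute ``log(1e-12)`` rather than -inf so that downstream
    recursions stay finite.
    """
    if not 0 <= state < params.n_states:
        raise ParameterError(f"state index {state} out of range")
    if not (np.isfinite(age) and np.isfinite(weight)):
        raise ValueError("age and weight must be finite")
    if params.age_var[state] < VAR_FLOOR or params.ar_var[state] < VAR_FLOOR \
            or params.w0_var[state] < VAR_FLOOR:
        raise ParameterError("variance below floor")
    male = 1.0 if sex == 1 else 0.0
    ll = _log_normal(age, params.age_mean[state], params.age_var[state])
    ll += _log_cat(params.sex_probs[state, sex])
    ll += _log_cat(params.geno_probs[state, genotype])
    if prev_weight is None:
        mean = params.w0_intercept[state] + params.w0_male[state] * male
        ll += _log_normal(weight, mean, params.w0_var[state])
    else:
        mean = (params.ar_intercept[state] + params.ar_male[state] * male
                + params.ar_slope[state] * prev_weight)
        ll += _log_normal(weight, mean, params.ar_var[state])
    return float(ll)


# ---------------------------------------------------------------------------
# batched padded representation
# ---------------------------------------------------------------------------


class _Batch:
    """Padded array view of a list of ObservationSequence."""

    def __init__(self, data: list[ObservationSequence]):
        if not data:
            raise ValueError("need at least one sequence")
        self.n = len(data)
        self.lengths = np.array([len(s) for s in data], dtype=int)
        if np.any(self.lengths < 1):
            raise ValueError("sequences must have at least one visit")
        self.kmax = int(self.lengths.max())
        self.ages = np.zeros((self.n, self.kmax))
        self.weights = np.zeros((self.n, self.kmax))
        self.mask = np.zeros((self.n, self.kmax), dtype=bool)
        self.sex = np.array([s.sex for s in data], dtype=int)
        self.geno = np.array([s.genotype for s in data], dtype=int)
        self.ids = [s.mouse_id for s in data]
        for s_i, seq in enumerate(data):
            k = len(seq)
            self.ages[s_i, :k] = seq.ages
            self.weights[s_i, :k] = seq.weights
            self.mask[s_i, :k] = True

    def log_emissions(self, params: AHMMParams) -> np.ndarray:
        """(n, kmax, N) log emission densities; 0 on padded slots."""
        N = params.n_states
        age = self.ages[:, :, None]                        # (n, k, 1)
        B = _log_normal(age, params.age_mean[None, None, :],
                        params.age_var[None, None, :])
        static = (_log_cat(params.sex_probs)[:, self.sex].T
                  + _log_cat(params.geno_probs)[:, self.geno].T)  # (n, N)
        B += static[:, None, :]
        male = (self.sex == 1).astype(float)[:, None]       # (n, 1)
        w = self.weights
        # first visit
        mean0 = params.w0_intercept[None, :] + params.w0_male[None, :] * male
        B[:, 0, :] += _log_normal(w[:, 0:1], mean0[:, None, :][:, 0, :],
                                  params.w0_var[None, :])
        if self.kmax > 1:
            prev = w[:, :-1, None]
            mean = (params.ar_intercept[None, None, :]
                    + params.ar_male[None, None, :] * male[:, :, None]
                    + params.ar_slope[None, None, :] * prev)
            B[:, 1:, :] += _log_normal(w[:, 1:, None], mean,
                                       params.ar_var[None, None, :])
        B[~self.mask] = 0.0
        if not np.all(np.isfinite(B[self.mask])):
            raise InferenceError("non-finite emission log-density encountered")
        return B


def _batch_forward_backward(batch: _Batch, params: AHMMParams):
    """Log-space forward-backward over a padded batch.

    Returns (gamma, xi_sum, loglik) where gamma is (n, kmax, N) posteriors
    (zero on padding), xi_sum is (n, N, N) summed pairwise posteriors, and
    loglik is (n,) per-sequence log-likelihood.
    """
    N = params.n_states
    n, kmax = batch.n, batch.kmax
    B = batch.log_emissions(params)
    logA = _log_cat(params.A)
    logpi = _log_cat(params.pi)

    alpha = np.full((n, kmax, N), -np.inf)
    alpha[:, 0, :] = logpi[None, :] + B[:, 0, :]
    for t in range(1, kmax):
        step = logsumexp(alpha[:, t - 1, :, None] + logA[None, :, :], axis=1)
        upd = step + B[:, t, :]
        active = batch.mask[:, t]
        alpha[:, t, :] = np.where(active[:, None], upd, alpha[:, t - 1, :])

    loglik = logsumexp(alpha[:, -1, :], axis=1)
    if not np.all(np.isfinite(loglik)):
        bad = [batch.ids[i] for i in np.where(~np.isfinite(loglik))[0]]
        raise InferenceError(f"zero total likelihood for sequences {bad}")

    beta = np.zeros((n, kmax, N))
    last = batch.lengths - 1
    for t in range(kmax - 2, -1, -1):
        step = logsumexp(logA[None, :, :] + (B[:, t + 1, None, :]
                                             + beta[:, t + 1, None, :]), axis=2)
        # beta is 0 at each sequence's own last visit; only visits strictly
        # before the last propagate
        active = t < last
        beta[:, t, :] = np.where(active[:, None], step, 0.0)

    log_gamma = alpha + beta - loglik[:, None, None]
    gamma = np.exp(log_gamma)
    gamma[~batch.mask] = 0.0
    # renormalize per visit against accumulated float error
    norm = gamma.sum(axis=2, keepdims=True)
    np.divide(gamma, norm, out=gamma, where=norm > 0)

    xi_sum = np.zeros((n, N, N))
    for t in range(kmax - 1):
        active = (t + 1) <= last
        if not np.any(active):
            continue
        log_xi = (alpha[:, t, :, None] + logA[None, :, :]
                  + B[:, t + 1, None, :] + beta[:, t + 1, None, :]
                  - loglik[:, None, None])
        xi_t = np.exp(log_xi)
        xi_t[~active] = 0.0
        s = xi_t.sum(axis=(1, 2), keepdims=True)
        np.divide(xi_t, s, out=xi_t, where=s > 0)
        xi_sum += xi_t
    return gamma, xi_sum, loglik


def forward_backward(seq: ObservationSequence, params: AHMMParams):
    """Exact smoothed inference for one sequence.

    Returns ``(gamma, xi, loglik)``: per-visit state posteriors (k, N),
    pairwise transition posteriors (k-1, N, N), and the sequence
    log-likelihood.  Equivalent to junction-tree inference on this chain.
    """
    params.validate()
    batch = _Batch([seq])
    N = params.n_states
    k = len(seq)
    B = batch.log_emissions(params)
    logA = _log_cat(params.A)
    gamma, _, loglik = _batch_forward_backward(batch, params)
    gamma = gamma[0, :k, :]
    # per-step xi for the single sequence (the batch helper sums over t)
    alpha = np.full((k, N), -np.inf)
    alpha[0] = _log_cat(params.pi) + B[0, 0]
    for t in range(1, k):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + logA, axis=0) + B[0, t]
    beta = np.zeros((k, N))
    for t in range(k - 2, -1, -1):
        beta[t] = logsumexp(logA + B[0, t + 1][None, :] + beta[t + 1][None, :],
                            axis=1)
    ll = float(loglik[0])
    xi = np.zeros((max(k - 1, 0), N, N))
    for t in range(k - 1):
        log_xi = alpha[t][:, None] + logA + B[0, t + 1][None, :] + beta[t + 1][None, :] - ll
        xi[t] = np.exp(log_xi)
        xi[t] /= xi[t].sum()
    return gamma, xi, ll


def sequence_loglik(data: list[ObservationSequence], params: AHMMParams) -> float:
    """Total log-likelihood of a dataset (sum over independent sequences)."""
    _, _, ll = _batch_forward_backward(_Batch(data), params)
    return float(ll.sum())


def viterbi(seq: ObservationSequence, params: AHMMParams) -> np.ndarray:
    """Most probable state path; ties broken toward the lower state index."""
    params.validate()
    batch = _Batch([seq])
    B = batch.log_emissions(params)[0]
    k = len(seq)
    N = params.n_states
    logA = _log_cat(params.A)
    delta = np.zeros((k, N))
    back = np.zeros((k, N), dtype=int)
    delta[0] = _log_cat(params.pi) + B[0]
    for t in range(1, k):
        cand = delta[t - 1][:, None] + logA          # (from, to)
        back[t] = np.argmax(cand, axis=0)            # first max -> lower index
        delta[t] = cand[back[t], np.arange(N)] + B[t]
    path = np.zeros(k, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(k - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _weighted_lstsq(Z: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve argmin_b sum w (y - Zb)^2 via normal equations with tiny ridge."""
    sw = np.sqrt(np.maximum(w, 0.0))
    Zw = Z * sw[:, None]
    yw = y * sw
    G = Zw.T @ Zw
    G[np.diag_indices_from(G)] += 1e-9
    return np.linalg.solve(G, Zw.T @ yw)


def _kmeans_1d(x: np.ndarray, k: int, rng: np.random.Generator,
               n_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's algorithm in 1D from jittered quantile seeds.

    Returns (centers, within-cluster variances), centers ascending.
    """
    qs = np.clip((np.arange(k) + 0.5) / k + rng.uniform(-0.25, 0.25, size=k) / k,
                 0.01, 0.99)
    centers = np.quantile(x, np.sort(qs))
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = assign == j
            if sel.any():
                new[j] = x[sel].mean()
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    pooled = max(float(x.var()), VAR_FLOOR * 10)
    variances = np.array([
        x[assign == j].var() if (assign == j).sum() > 1 else pooled
        for j in range(k)
    ])
    order = np.argsort(centers)
    return centers[order], np.maximum(variances[order], VAR_FLOOR * 10)


def _init_params(batch: _Batch, n_states: int, rng: np.random.Generator) -> AHMMParams:
    """Randomized initialization around a 1D weight clustering.

    Weight centers come from jittered k-means on all recorded weights, with
    emission variances at the within-cluster spread so states separate by
    weight level from the first E-step (a diffuse pooled variance tends to
    collapse into a single random-walk state).  The transition matrix starts
    sticky with Dirichlet jitter; age and the categoricals start near their
    pooled moments.
    """
    N = n_states
    w_all = batch.weights[batch.mask]
    a_all = batch.ages[batch.mask]
    w_sd = max(float(w_all.std()), 0.5)

    pi = np.full(N, 1.0 / N)
    stay = rng.uniform(0.5, 0.85)
    A = uniform_sticky = np.full((N, N), (1.0 - stay) / max(N - 1, 1))
    np.fill_diagonal(A, stay if N > 1 else 1.0)
    A = A + rng.dirichlet(np.full(N, 2.0), size=N) * 0.2
    A /= A.sum(axis=1, keepdims=True)

    centers, wvar = _kmeans_1d(w_all, N, rng)
    centers = centers + rng.normal(0, 0.05 * w_sd, size=N)

    age_mean = np.full(N, a_all.mean()) + rng.normal(0, 0.2 * max(a_all.std(), 0.5), N)
    age_var = np.full(N, max(a_all.var(), VAR_FLOOR * 10))

    sex_marg = np.bincount(batch.sex, minlength=2).astype(float) + 1.0
    geno_marg = np.bincount(batch.geno, minlength=3).astype(float) + 1.0
    sex_probs = sex_marg / sex_marg.sum() + rng.uniform(0, 0.1, size=(N, 2))
    sex_probs /= sex_probs.sum(axis=1, keepdims=True)
    geno_probs = geno_marg / geno_marg.sum() + rng.uniform(0, 0.1, size=(N, 3))
    geno_probs /= geno_probs.sum(axis=1, keepdims=True)

    phi = rng.uniform(0.1, 0.7, size=N)
    alpha = centers * (1.0 - phi)
    delta = rng.normal(0, 0.2, size=N)
    ar_var = wvar * rng.uniform(0.8, 1.5, size=N)
    return AHMMParams(
        pi=pi, A=A, age_mean=age_mean, age_var=age_var,
        sex_probs=sex_probs, geno_probs=geno_probs,
        ar_intercept=alpha, ar_male=delta, ar_slope=phi, ar_var=ar_var,
        w0_intercept=centers.copy(), w0_male=np.full(N, w_sd * 0.3),
        w0_var=np.maximum(wvar * 2.0, VAR_FLOOR * 10),
    )


def _m_step(batch: _Batch, gamma: np.ndarray, xi_sum: np.ndarray,
            old: AHMMParams, rng: np.random.Generator) -> AHMMParams:
    N = gamma.shape[2]
    mask = batch.mask
    male = (batch.sex == 1).astype(float)

    pi = gamma[:, 0, :].sum(axis=0)
    pi = np.maximum(pi, PROB_FLOOR)
    pi /= pi.sum()

    A = xi_sum.sum(axis=0)
    A = np.maximum(A, PROB_FLOOR)
    A /= A.sum(axis=1, keepdims=True)

    g_flat = gamma[mask]                      # (M, N) responsibilities per visit
    ages = batch.ages[mask]
    wsum = g_flat.sum(axis=0)                 # (N,)

    empty = wsum < 1e-6
    age_mean = old.age_mean.copy()
    age_var = old.age_var.copy()
    sex_probs = old.sex_probs.copy()
    geno_probs = old.geno_probs.copy()
    ar = np.stack([old.ar_intercept, old.ar_male, old.ar_slope], axis=1)
    ar_var = old.ar_var.copy()
    w0 = np.stack([old.w0_intercept, old.w0_male], axis=1)
    w0_var = old.w0_var.copy()

    safe = ~empty
    if np.any(safe):
        age_mean[safe] = (g_flat[:, safe] * ages[:, None]).sum(axis=0) / wsum[safe]
        age_var[safe] = np.maximum(
            (g_flat[:, safe] * (ages[:, None] - age_mean[None, safe]) ** 2).sum(axis=0)
            / wsum[safe], VAR_FLOOR)

    # static covariates: each visit re-emits the mouse's sex/genotype
    sex_onehot = np.eye(2)[batch.sex]         # (n, 2)
    geno_onehot = np.eye(3)[batch.geno]
    g_per_mouse = gamma.sum(axis=1)           # (n, N) total responsibility mass
    sp = g_per_mouse.T @ sex_onehot + PROB_FLOOR
    gp = g_per_mouse.T @ geno_onehot + PROB_FLOOR
    sex_probs[safe] = (sp / sp.sum(axis=1, keepdims=True))[safe]
    geno_probs[safe] = (gp / gp.sum(axis=1, keepdims=True))[safe]

    # AR regression on visits t>=1
    if batch.kmax > 1:
        m1 = mask[:, 1:]
        y = batch.weights[:, 1:][m1]
        prev = batch.weights[:, :-1][m1]
        male_rep = np.broadcast_to(male[:, None], m1.shape)[m1]
        Z = np.column_stack([np.ones_like(y), male_rep, prev])
        g1 = gamma[:, 1:, :][m1]              # (M1, N)
        for i in range(N):
            if empty[i] or g1[:, i].sum() < 1e-6:
                continue
            beta = _weighted_lstsq(Z, y, g1[:, i])
            resid = y - Z @ beta
            ar[i] = beta
            ar_var[i] = max((g1[:, i] * resid ** 2).sum() / g1[:, i].sum(), VAR_FLOOR)

    # first-visit Gaussian
    y0 = batch.weights[:, 0]
    Z0 = np.column_stack([np.ones_like(y0), male])
    g0 = gamma[:, 0, :]
    for i in range(N):
        wi = g0[:, i]
        if wi.sum() < 1e-6:
            continue
        beta0 = _weighted_lstsq(Z0, y0, wi)
        resid0 = y0 - Z0 @ beta0
        w0[i] = beta0
        w0_var[i] = max((wi * resid0 ** 2).sum() / wi.sum(), VAR_FLOOR)

    if np.any(empty):
        # re-seed starved states from a random sequence segment
        for i in np.where(empty)[0]:
            logger.warning("EM: state %d received ~zero responsibility; re-seeding", i)
            s = int(rng.integers(batch.n))
            k = batch.lengths[s]
            t = int(rng.integers(k))
            age_mean[i] = batch.ages[s, t]
            age_var[i] = max(batch.ages[mask].var(), VAR_FLOOR * 10)
            w0[i] = (batch.weights[s, 0], 0.0)
            w0_var[i] = max(batch.weights[mask].var(), VAR_FLOOR * 10)
            ar[i] = (batch.weights[s, t] * 0.5, 0.0, 0.5)
            ar_var[i] = w0_var[i]

    return AHMMParams(
        pi=pi, A=A, age_mean=age_mean, age_var=age_var,
        sex_probs=sex_probs, geno_probs=geno_probs,
        ar_intercept=ar[:, 0], ar_male=ar[:, 1], ar_slope=ar[:, 2], ar_var=ar_var,
        w0_intercept=w0[:, 0], w0_male=w0[:, 1], w0_var=w0_var,
    )


def em_fit(
    data: list[ObservationSequence],
    n_states: int,
    n_iters: int = 1500,
    seed: int | np.random.Generator | None = None,
    rel_tol: float = 1e-8,
    init_params: AHMMParams | None = None,
):
    """Fit the AHMM by EM from one random initialization.

    Returns ``(params, trace)`` where trace[i] is the total log-likelihood
    of the parameters entering iteration i; the trace is non-decreasing
    (within float tolerance) and ends with the final parameters' likelihood.
    Early-stops when the relative improvement falls below ``rel_tol``.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    batch = _Batch(data)
    params = init_params if init_params is not None else _init_params(batch, n_states, rng)
    params.validate()
    trace: list[float] = []
    for _ in range(n_iters):
        gamma, xi_sum, loglik = _batch_forward_backward(batch, params)
        ll = float(loglik.sum())
        if trace and abs(ll - trace[-1]) < rel_tol * abs(trace[-1]):
            trace.append(ll)
            break
        trace.append(ll)
        params = _m_step(batch, gamma, xi_sum, params, rng)
    else:
        _, _, loglik = _batch_forward_backward(batch, params)
        trace.append(float(loglik.sum()))
    return params, trace


def canonical_relabel(params: AHMMParams) -> tuple[AHMMParams, list, dict]:
    """Sort states by stationary weight level ascending; label A, B, C, ...

    Returns (relabeled params, labels by new index, map raw index -> label).
    """
    level = params.stationary_weight_level()
    order = np.argsort(level, kind="stable")
    relabeled = params.permuted(order)
    labels = [STATE_ALPHABET[i] for i in range(params.n_states)]
    raw_to_label = {int(order[i]): STATE_ALPHABET[i] for i in range(params.n_states)}
    return relabeled, labels, raw_to_label


def fit_with_restarts(
    data: list[ObservationSequence],
    n_states: int = 10,
    n_iters: int = 1500,
    n_restarts: int = 10,
    master_seed: int = 0,
    rel_tol: float = 1e-8,
) -> FitResult:
    """Run ``n_restarts`` independent EM fits and keep the best by likelihood.

    Restart r uses the generator seeded by ``[master_seed, r]`` so results are
    reproducible from the master seed alone.  Failed restarts are logged and
    skipped; if all fail an InferenceError is raised.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    finals: list[float] = []
    traces: list[list] = []
    best_params = None
    best_ll = -np.inf
    best_r = -1
    for r in range(n_restarts):
        rng = np.random.default_rng([master_seed, r])
        try:
            params, trace = em_fit(data, n_states, n_iters=n_iters, seed=rng,
                                   rel_tol=rel_tol)
        except (InferenceError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            logger.warning("restart %d failed: %s", r, exc)
            finals.append(np.nan)
            traces.append([])
            continue
        finals.append(trace[-1])
        traces.append(trace)
        if trace[-1] > best_ll:
            best_ll = trace[-1]
            best_params = params
            best_r = r
    if best_params is None:
        raise InferenceError("all EM restarts failed")
    relabeled, labels, raw_map = canonical_relabel(best_params)
    return FitResult(
        params=relabeled,
        restart_logliks=finals,
        traces=traces,
        best_restart=best_r,
        master_seed=master_seed,
        state_labels=labels,
        relabel_map=raw_map,
    )
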