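"""Independent oracles: exhaustive path enumeration and direct formulas.

Everything here is computed from scipy / first principles without touching
the package's recursions, so the tests compare two independent routes.
"""

import itertools

import numpy as np
from scipy.stats import norm


def emission_logpdf_oracle(params, state, age, weight, prev_weight, sex, genotype):
    """Component-wise emission log-density via scipy distributions."""
    male = 1.0 if sex == 1 else 0.0
    ll = norm.logpdf(age, params.age_mean[state], np.sqrt(params.age_var[state]))
    ll += np.log(max(params.sex_probs[state, sex], 1e-12))
    ll += np.log(max(params.geno_probs[state, genotype], 1e-12))
    if prev_weight is None:
        mu = params.w0_intercept[state] + params.w0_male[state] * male
        sd = np.sqrt(params.w0_var[state])
    else:
        mu = (params.ar_intercept[state] + params.ar_male[state] * male
              + params.ar_slope[state] * prev_weight)
        sd = np.sqrt(params.ar_var[state])
    return float(ll + norm.logpdf(weight, mu, sd))


def enumerate_posteriors(params, seq):
    """(gamma, xi, loglik, best_path) by summing over every state path.

    Joint log-probabilities are assembled per path from the initial law, the
    transition entries and the per-visit emission densities (scipy), never
    via the package's recursions.
    """
    N = params.n_states
    k = len(seq)
    E = np.array([[emission_logpdf_oracle(params, s, seq.ages[t], seq.weights[t],
                                          None if t == 0 else seq.weights[t - 1],
                                          seq.sex, seq.genotype)
                   for s in range(N)] for t in range(k)])
    logpi = np.log(np.maximum(params.pi, 1e-12))
    logA = np.log(np.maximum(params.A, 1e-12))
    paths = np.array(list(itertools.product(range(N), repeat=k)), dtype=int)
    logps = logpi[paths[:, 0]] + E[0, paths[:, 0]]
    for t in range(1, k):
        logps += logA[paths[:, t - 1], paths[:, t]] + E[t, paths[:, t]]
    m = logps.max()
    probs = np.exp(logps - m)
    total = probs.sum()
    loglik = m + np.log(total)
    gamma = np.zeros((k, N))
    xi = np.zeros((k - 1, N, N))
    for t in range(k):
        np.add.at(gamma[t], paths[:, t], probs)
    for t in range(k - 1):
        np.add.at(xi[t], (paths[:, t], paths[:, t + 1]), probs)
    gamma /= total
    xi /= total
    best = paths[int(np.argmax(logps))]
    return gamma, xi, float(loglik), best.copy()


def km_oracle_table(times, events):
    """Product-limit survival values via the direct formula (sorted inputs)."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times)[order]
    events = np.asarray(events)[order]
    n = len(times)
    out = []
    s = 1.0
    i = 0
    while i < n:
        t = times[i]
        d = 0
        at_risk = n - i
        while i < n and times[i] == t:
            d += int(events[i])
            i += 1
        if d:
            s *= 1 - d / at_risk
            out.append((float(t), s))
    return out
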