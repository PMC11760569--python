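"""Unit and property tests for the autoregressive HMM core."""

import numpy as np
import pytest

from apoetraj.ahmm import (
    AHMMParams, LOG_ZERO, ObservationSequence, ParameterError, canonical_relabel,
    em_fit, emission_logdensity, fit_with_restarts, forward_backward,
    sequence_loglik, viterbi,
)

from conftest import random_params, random_sequence
from oracles import emission_logpdf_oracle, enumerate_posteriors


def uniform_params(n_states, **overrides):
    N = n_states
    base = dict(
        pi=np.full(N, 1 / N), A=np.full((N, N), 1 / N),
        age_mean=np.full(N, 15.0), age_var=np.full(N, 1.0),
        sex_probs=np.full((N, 2), 0.5), geno_probs=np.full((N, 3), 1 / 3),
        ar_intercept=np.full(N, 15.0), ar_male=np.zeros(N),
        ar_slope=np.full(N, 0.5), ar_var=np.full(N, 1.0),
        w0_intercept=np.full(N, 30.0), w0_male=np.zeros(N),
        w0_var=np.full(N, 1.0),
    )
    base.update(overrides)
    return AHMMParams(**base)


class TestEmission:
    def test_closed_form_at_means(self):
        # both Gaussians at their mean with unit variance, uniform categoricals
        p = uniform_params(2)
        val = emission_logdensity(p, 0, age=15.0, weight=30.0, prev_weight=None,
                                  sex=0, genotype=0)
        expected = -np.log(2 * np.pi) + np.log(0.5) + np.log(1 / 3)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_category_is_large_negative_sentinel(self):
        p = uniform_params(2, sex_probs=np.array([[1.0, 0.0], [0.5, 0.5]]))
        val = emission_logdensity(p, 0, 15.0, 30.0, None, sex=1, genotype=0)
        assert np.isfinite(val)
        assert val < LOG_ZERO / 2  # carries the log(1e-12) sentinel

    def test_matches_componentwise_oracle(self, rng):
        for _ in range(25):
            p = random_params(rng, 3)
            seq = random_sequence(rng, 4)
            for t in range(len(seq)):
                prev = None if t == 0 else seq.weights[t - 1]
                for i in range(3):
                    mine = emission_logdensity(p, i, seq.ages[t], seq.weights[t],
                                               prev, seq.sex, seq.genotype)
                    ref = emission_logpdf_oracle(p, i, seq.ages[t], seq.weights[t],
                                                 prev, seq.sex, seq.genotype)
                    assert mine == pytest.approx(ref, abs=1e-10)

    def test_invalid_state_and_variance_raise(self):
        p = uniform_params(2)
        with pytest.raises(ParameterError):
            emission_logdensity(p, 5, 15.0, 30.0, None, 0, 0)
        p.ar_var[:] = 1e-9
        with pytest.raises(ParameterError):
            emission_logdensity(p, 0, 15.0, 30.0, 25.0, 0, 0)


class TestForwardBackward:
    def test_single_state_posteriors_and_loglik(self, rng):
        p = random_params(rng, 1)
        seq = random_sequence(rng, 5)
        gamma, xi, ll = forward_backward(seq, p)
        assert np.allclose(gamma, 1.0)
        direct = sum(
            emission_logdensity(p, 0, seq.ages[t], seq.weights[t],
                                None if t == 0 else seq.weights[t - 1],
                                seq.sex, seq.genotype)
            for t in range(5))
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_identical_states_give_symmetric_posteriors(self, rng):
        p = uniform_params(2)
        seq = random_sequence(rng, 6)
        gamma, xi, _ = forward_backward(seq, p)
        assert np.allclose(gamma, 0.5, atol=1e-12)
        assert np.allclose(xi, 0.25, atol=1e-12)

    @pytest.mark.parametrize("n_states,k", [(2, 3), (3, 4), (4, 5), (2, 6)])
    def test_matches_path_enumeration(self, rng, n_states, k):
        for _ in range(10):
            p = random_params(rng, n_states)
            seq = random_sequence(rng, k)
            gamma, xi, ll = forward_backward(seq, p)
            g_ref, xi_ref, ll_ref, _ = enumerate_posteriors(p, seq)
            assert ll == pytest.approx(ll_ref, abs=1e-10)
            assert np.allclose(gamma, g_ref, atol=1e-10)
            assert np.allclose(xi, xi_ref, atol=1e-10)

    def test_posteriors_normalized(self, rng):
        p = random_params(rng, 3)
        seq = random_sequence(rng, 8)
        gamma, xi, _ = forward_backward(seq, p)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-10)

    def test_total_loglik_sums_over_sequences(self, rng):
        p = random_params(rng, 3)
        seqs = [random_sequence(rng, k, f"m{k}") for k in (3, 5, 9)]
        total = sequence_loglik(seqs, p)
        parts = [forward_backward(s, p)[2] for s in seqs]
        assert total == pytest.approx(sum(parts), abs=1e-8)

    def test_loglik_invariant_under_relabeling(self, rng):
        p = random_params(rng, 4)
        seqs = [random_sequence(rng, 5, f"m{i}") for i in range(4)]
        relabeled, _, _ = canonical_relabel(p)
        assert sequence_loglik(seqs, p) == pytest.approx(
            sequence_loglik(seqs, relabeled), abs=1e-8)


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        p = random_params(rng, 1)
        seq = random_sequence(rng, 4)
        assert np.array_equal(viterbi(seq, p), np.zeros(4, dtype=int))

    @pytest.mark.parametrize("n_states,k", [(2, 4), (3, 4), (4, 5)])
    def test_matches_exhaustive_argmax(self, rng, n_states, k):
        for _ in range(10):
            p = random_params(rng, n_states)
            seq = random_sequence(rng, k)
            path = viterbi(seq, p)
            _, _, _, best = enumerate_posteriors(p, seq)
            assert np.array_equal(path, best)

    def test_ties_break_to_lower_state(self, rng):
        p = uniform_params(3)
        seq = random_sequence(rng, 5)
        assert np.array_equal(viterbi(seq, p), np.zeros(5, dtype=int))


def _simulated_dataset(rng, n=40, k=6):
    seqs = []
    for i in range(n):
        sex = int(rng.integers(2))
        level = rng.choice([20.0, 32.0])
        w = [level + 2 * sex + rng.normal(0, 1)]
        for _ in range(k - 1):
            w.append(0.5 * level + 1.0 * sex + 0.5 * w[-1] + rng.normal(0, 1))
        ages = np.sort(rng.uniform(5, 20, k))
        while len(np.unique(ages)) < k:
            ages = np.sort(rng.uniform(5, 20, k))
        seqs.append(ObservationSequence(f"m{i}", sex, int(rng.integers(3)),
                                        ages, np.array(w)))
    return seqs


class TestEM:
    def test_single_state_equals_weighted_ols(self, rng):
        """With one state the AR M-step is plain least squares on
        (1, male, prev_weight); the EM fixed point must match it."""
        seqs = _simulated_dataset(rng, n=30, k=6)
        params, _ = em_fit(seqs, n_states=1, n_iters=5, seed=0)
        y, Z = [], []
        for s in seqs:
            male = float(s.sex == 1)
            for t in range(1, len(s)):
                y.append(s.weights[t])
                Z.append([1.0, male, s.weights[t - 1]])
        beta, *_ = np.linalg.lstsq(np.array(Z), np.array(y), rcond=None)
        fitted = np.array([params.ar_intercept[0], params.ar_male[0],
                           params.ar_slope[0]])
        assert np.allclose(fitted, beta, atol=1e-6)

    def test_loglik_trace_nondecreasing(self, rng):
        seqs = _simulated_dataset(rng, n=40, k=6)
        for seed in range(3):
            _, trace = em_fit(seqs, n_states=3, n_iters=60, seed=seed)
            t = np.array(trace)
            tol = 1e-6 * np.abs(t)[:-1]
            assert np.all(np.diff(t) >= -tol)

    def test_em_from_good_start_does_not_decrease(self, rng):
        seqs = _simulated_dataset(rng, n=40, k=6)
        p0, trace0 = em_fit(seqs, n_states=2, n_iters=80, seed=1)
        _, trace1 = em_fit(seqs, n_states=2, n_iters=3, seed=2, init_params=p0)
        assert trace1[-1] >= trace0[-1] - 1e-6 * abs(trace0[-1])


class TestRestarts:
    def test_single_restart_equals_em_fit(self, rng):
        seqs = _simulated_dataset(rng, n=25, k=5)
        fit = fit_with_restarts(seqs, n_states=2, n_iters=40, n_restarts=1,
                                master_seed=7)
        params, trace = em_fit(seqs, n_states=2, n_iters=40,
                               seed=np.random.default_rng([7, 0]))
        relabeled, _, _ = canonical_relabel(params)
        assert fit.log_likelihood == pytest.approx(trace[-1], abs=1e-9)
        assert np.allclose(fit.params.A, relabeled.A)

    def test_deterministic_given_master_seed(self, rng):
        seqs = _simulated_dataset(rng, n=25, k=5)
        f1 = fit_with_restarts(seqs, n_states=2, n_iters=30, n_restarts=3,
                               master_seed=11)
        f2 = fit_with_restarts(seqs, n_states=2, n_iters=30, n_restarts=3,
                               master_seed=11)
        assert f1.restart_logliks == f2.restart_logliks
        assert np.array_equal(f1.params.A, f2.params.A)

    def test_best_restart_has_max_loglik(self, rng):
        seqs = _simulated_dataset(rng, n=25, k=5)
        fit = fit_with_restarts(seqs, n_states=2, n_iters=30, n_restarts=4,
                                master_seed=3)
        finite = [x for x in fit.restart_logliks if np.isfinite(x)]
        assert fit.log_likelihood == max(finite)

    def test_canonical_labels_sorted_by_weight_level(self, rng):
        seqs = _simulated_dataset(rng, n=30, k=6)
        fit = fit_with_restarts(seqs, n_states=2, n_iters=60, n_restarts=2,
                                master_seed=5)
        levels = fit.params.stationary_weight_level()
        assert np.all(np.diff(levels) >= 0)
        assert fit.state_labels == ["A", "B"]

    def test_roundtrip_json(self, rng, tmp_path):
        from apoetraj.ahmm import FitResult
        seqs = _simulated_dataset(rng, n=20, k=5)
        fit = fit_with_restarts(seqs, n_states=2, n_iters=20, n_restarts=2,
                                master_seed=1)
        fit.to_json(tmp_path / "fit.json")
        back = FitResult.from_json(tmp_path / "fit.json")
        assert np.allclose(back.params.A, fit.params.A)
        assert back.state_labels == fit.state_labels
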